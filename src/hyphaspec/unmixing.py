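"""SIMPLISMA pure-variable selection and non-negative MCR-ALS factorization.

The pixel-by-wavenumber matrix D is modelled as D ≈ C·Sᵀ with C ≥ 0
(per-pixel contributions) and S ≥ 0 (component spectra, columns scaled to
unit maximum).  Each alternating half-step is an *exact* non-negative
least-squares minimizer, which guarantees a non-increasing lack-of-fit
sequence; for the small component counts used here (k ≤ 6) the row-wise NNLS
is solved by enumerating active sets, vectorized over all rows at once.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneracyError, ValidationError
from .spectral_core import HyperspectralCube, Spectrum, WavenumberGrid

_ENUM_MAX_K = 6


@dataclass
class MixtureMatrix:
    """Non-negative data matrix (n_pixels × n_wavenumbers) plus the mapping
    from matrix row back to cube coordinates."""

    D: np.ndarray
    pixel_index: np.ndarray  # (n_pixels, 2) of (row, col)
    grid: WavenumberGrid

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.ndim != 2 or D.shape[1] != len(self.grid):
            raise ValidationError("D must be n_pixels × n_wavenumbers")
        row_sums = np.abs(D).sum(axis=1)
        if np.any(row_sums == 0):
            raise ValidationError("D contains all-zero rows; mask them before assembly")
        self.D = D
        self.pixel_index = np.asarray(self.pixel_index, dtype=int)

    @classmethod
    def from_cube(cls, cube: HyperspectralCube) -> "MixtureMatrix":
        """Flatten a preprocessed cube, excluding masked and all-zero pixels."""
        rows, cols = cube.rows, cube.cols
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        keep = np.ones((rows, cols), dtype=bool)
        if cube.mask is not None:
            keep &= ~cube.mask
        flat = cube.data.reshape(rows * cols, -1)
        keepf = keep.ravel() & (np.abs(flat).sum(axis=1) > 0)
        idx = np.stack([rr.ravel()[keepf], cc.ravel()[keepf]], axis=1)
        return cls(D=flat[keepf], pixel_index=idx, grid=cube.grid)


@dataclass
class UnmixingResult:
    S: np.ndarray                # n_wavenumbers × k, columns unit-maximum
    C: np.ndarray                # n_pixels × k
    k: int
    lof_percent: float
    n_iterations: int
    converged: bool
    pure_variables: np.ndarray
    lof_history: np.ndarray = field(default_factory=lambda: np.array([]))
    grid: WavenumberGrid | None = None
    pixel_index: np.ndarray | None = None

    def component_spectrum(self, j: int, label: str = "") -> Spectrum:
        if self.grid is None:
            raise ValidationError("result carries no wavenumber grid")
        return Spectrum(self.grid, self.S[:, j].copy(), label or f"component_{j}")

    def diagnostics_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "lof_percent": self.lof_percent,
                "n_iterations": self.n_iterations,
                "converged": self.converged,
                "pure_variables": self.pure_variables.tolist(),
            }
        )


def lack_of_fit(D: np.ndarray, C: np.ndarray, S: np.ndarray) -> float:
    """100·sqrt(Σ(D − C·Sᵀ)² / ΣD²), the standard MCR diagnostic."""
    D = np.asarray(D, dtype=float)
    denom = float(np.sum(D * D))
    if denom == 0:
        raise DegeneracyError("ΣD² = 0: lack of fit undefined")
    resid = D - C @ S.T
    return 100.0 * float(np.sqrt(np.sum(resid * resid) / denom))


# --------------------------------------------------------------------------
# Exact multi-row NNLS


def nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min‖B − A·Xᵀ‖² s.t. X ≥ 0 for every row of X.

    A is m×k (shared design), B is m×n (one column per problem); returns X of
    shape n×k.  For k ≤ 6 all 2^k active sets are enumerated — each candidate
    is the unconstrained LS solution on its support, so the true NNLS optimum
    (whose support solution is stationary by KKT) is among the feasible
    candidates and is selected by maximal objective decrease.  Larger k falls
    back to scipy's active-set solver per column.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    m, k = A.shape
    n = B.shape[1]
    if k > _ENUM_MAX_K:
        from scipy.optimize import nnls as _scipy_nnls

        X = np.zeros((n, k))
        for j in range(n):
            X[j], _ = _scipy_nnls(A, B[:, j])
        return X

    G = A.T @ A                      # k×k
    H = A.T @ B                      # k×n
    best_obj = np.zeros(n)           # objective gain −f(x) = xᵀH at stationarity
    best_X = np.zeros((n, k))
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(k), size):
            P = list(subset)
            G_P = G[np.ix_(P, P)]
            try:
                X_P = np.linalg.solve(G_P, H[P])          # |P|×n
            except np.linalg.LinAlgError:
                X_P = np.linalg.pinv(G_P) @ H[P]
            feasible = np.all(X_P >= -1e-10, axis=0)
            obj = np.einsum("ij,ij->j", X_P, H[P])
            better = feasible & (obj > best_obj + 1e-15)
            if np.any(better):
                best_obj[better] = obj[better]
                best_X[better] = 0.0
                best_X[np.ix_(np.flatnonzero(better), P)] = X_P[:, better].T
    return np.maximum(best_X, 0.0)


# --------------------------------------------------------------------------
# SIMPLISMA


def simplisma(
    matrix: MixtureMatrix | np.ndarray, k: int, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Select k pure variables (wavenumber channels) by purity.

    Purity of column j is p_j = σ_j / (μ_j + α·max_j μ_j); after the first
    selection, candidates are weighted by the determinant of the
    correlation-around-the-origin matrix of the candidate column joined with
    the already-selected columns, which suppresses channels correlated with
    earlier picks.  Ties break to the lowest index.

    Returns ``(pure_variables, C0)`` where C0 holds the selected data columns
    scaled to unit maximum — the initial contribution estimates handed to
    :func:`mcr_als`.
    """
    D = matrix.D if isinstance(matrix, MixtureMatrix) else np.asarray(matrix, dtype=float)
    n_pix, n_wn = D.shape
    if not 1 <= k <= min(n_pix, n_wn):
        raise DegeneracyError(f"k={k} infeasible for a {n_pix}×{n_wn} matrix")
    mu = D.mean(axis=0)
    sigma = D.std(axis=0)
    if np.all(sigma == 0):
        raise DegeneracyError("all columns constant: no pure variables")
    purity = sigma / (mu + alpha * mu.max())

    norms = np.linalg.norm(D, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    Y = D / safe  # cosine-normalized columns (correlation around the origin)

    selected: list[int] = []
    for _ in range(k):
        if not selected:
            weights = np.ones(n_wn)
        else:
            Ysel = Y[:, selected]                     # n_pix × s
            base = Ysel.T @ Ysel                      # s×s
            cross = Ysel.T @ Y                        # s×n_wn
            diag = np.einsum("ij,ij->j", Y, Y)        # 1 per column (0 for zero cols)
            # det([[diag_j, cross_jᵀ], [cross_j, base]]) for every j at once
            try:
                sol = np.linalg.solve(base, cross)
            except np.linalg.LinAlgError:
                sol = np.linalg.pinv(base) @ cross
            weights = (diag - np.einsum("ij,ij->j", cross, sol)) * np.linalg.det(base)
            weights = np.maximum(weights, 0.0)
            weights[selected] = 0.0
        score = purity * weights
        pick = int(np.argmax(score))  # argmax returns the lowest index on ties
        selected.append(pick)

    pure = np.asarray(selected, dtype=int)
    C0 = D[:, pure].astype(float).copy()
    colmax = C0.max(axis=0)
    if np.any(colmax <= 0):
        raise DegeneracyError("selected pure variable has no positive signal")
    C0 /= colmax
    return pure, C0


# --------------------------------------------------------------------------
# MCR-ALS


def mcr_als(
    matrix: MixtureMatrix | np.ndarray,
    C0: np.ndarray | None = None,
    S0: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    pure_variables: np.ndarray | None = None,
) -> UnmixingResult:
    """Alternating non-negative least squares from an initial C0 (or S0).

    Each iteration solves S ← argmin‖D − C·Sᵀ‖ (S ≥ 0) then
    C ← argmin‖D − C·Sᵀ‖ (C ≥ 0), rescales S columns to unit maximum with the
    inverse scale folded into C, and records the lack of fit.  Stops when the
    relative LOF change drops below ``tol`` or after ``max_iter`` iterations
    (returned with ``converged=False``, not an exception).
    """
    if isinstance(matrix, MixtureMatrix):
        D = matrix.D
        grid = matrix.grid
        pixel_index = matrix.pixel_index
    else:
        D = np.asarray(matrix, dtype=float)
        grid = None
        pixel_index = None

    if (C0 is None) == (S0 is None):
        raise ValidationError("provide exactly one of C0 (contributions) or S0 (spectra)")
    C = None if C0 is None else np.asarray(C0, dtype=float).copy()
    S = None if S0 is None else np.asarray(S0, dtype=float).copy()
    init = C if C is not None else S
    if init.ndim != 2:
        raise ValidationError("initial estimate must be 2-D")
    k = init.shape[1]
    if np.any(init < 0):
        raise ValidationError("initial estimate must be non-negative")
    if np.any(init.max(axis=0) <= 0):
        raise DegeneracyError("initial estimate has an all-zero column")
    if np.linalg.matrix_rank(init) < k:
        raise DegeneracyError("initial estimate is rank-deficient")

    lof_history: list[float] = []
    lof_prev = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if C is not None:
            S = nnls_rows(C, D)                     # n_wn × k
        C = nnls_rows(S, D.T)                       # n_pix × k
        # fix the scale ambiguity: unit-maximum spectra
        scale = S.max(axis=0)
        ok = scale > 0
        S[:, ok] /= scale[ok]
        C[:, ok] *= scale[ok]
        lof = lack_of_fit(D, C, S)
        lof_history.append(lof)
        if np.isfinite(lof_prev) and abs(lof_prev - lof) < tol * max(lof, 1e-12):
            converged = True
            break
        lof_prev = lof

    return UnmixingResult(
        S=S,
        C=C,
        k=k,
        lof_percent=lof_history[-1],
        n_iterations=n_iter,
        converged=converged,
        pure_variables=np.asarray([] if pure_variables is None else pure_variables, dtype=int),
        lof_history=np.asarray(lof_history),
        grid=grid,
        pixel_index=pixel_index,
    )


def simplisma_mcr(
    matrix: MixtureMatrix | np.ndarray,
    k: int,
    alpha: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> UnmixingResult:
    """SIMPLISMA initialization followed by MCR-ALS: the standard pairing."""
    pure, C0 = simplisma(matrix, k, alpha)
    return mcr_als(matrix, C0=C0, max_iter=max_iter, tol=tol, pure_variables=pure)


# --------------------------------------------------------------------------
# Component matching (test/report utility)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_components(
    recovered: np.ndarray | UnmixingResult, truth: list[Spectrum] | np.ndarray
) -> tuple[tuple[int, ...], np.ndarray]:
    """Best pairing of recovered components to reference spectra.

    Exhaustive over permutations (k ≤ 4 in practice); maximizes total cosine
    similarity.  Returns ``(permutation, similarities)`` where
    ``permutation[i]`` is the recovered column matched to truth i.
    """
    S = recovered.S if isinstance(recovered, UnmixingResult) else np.asarray(recovered)
    if isinstance(truth, (list, tuple)):
        T = np.stack([t.absorbance for t in truth], axis=1)
    else:
        T = np.asarray(truth)
    if S.shape[1] != T.shape[1]:
        raise ValidationError(f"component counts differ: {S.shape[1]} vs {T.shape[1]}")
    k = S.shape[1]
    sim = np.array(
        [[cosine_similarity(T[:, i], S[:, j]) for j in range(k)] for i in range(k)]
    )
    best_perm, best_total = None, -np.inf
    for perm in itertools.permutations(range(k)):
        total = sum(sim[i, perm[i]] for i in range(k))
        if total > best_total:
            best_total, best_perm = total, perm
    return best_perm, np.array([sim[i, best_perm[i]] for i in range(k)])
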