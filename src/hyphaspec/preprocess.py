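"""Spectral preprocessing chain.

The pipeline applies, in order: atmospheric-gas correction, cropping to the
900–1800 cm⁻¹ fingerprint window, rubberband (lower convex hull) baseline
correction, and normalization to the cellulose CH-bend peak at 1370 cm⁻¹.
Also provides the generic peak detector used for band-position QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.signal import find_peaks

from .errors import (
    ConfigurationError,
    DegeneracyError,
    NormalizationError,
    RangeError,
)
from .spectral_core import HyperspectralCube, Spectrum, WavenumberGrid, resample_to_grid

_STEP_NAMES = ("atmosphere", "crop", "rubberband", "normalize")


@dataclass(frozen=True)
class PreprocessConfig:
    crop_lo: float = 900.0
    crop_hi: float = 1800.0
    anchor: float = 1370.0
    anchor_window: float = 15.0
    atmosphere_fit_region: tuple[float, float] = (1300.0, 1800.0)
    steps: tuple[str, ...] = _STEP_NAMES

    def __post_init__(self) -> None:
        if self.crop_lo >= self.crop_hi:
            raise ConfigurationError("crop_lo must be < crop_hi")
        if not self.crop_lo <= self.anchor <= self.crop_hi:
            raise ConfigurationError("anchor must lie inside the crop window")
        unknown = set(self.steps) - set(_STEP_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown preprocessing steps: {sorted(unknown)}")

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "crop_lo": self.crop_lo,
                "crop_hi": self.crop_hi,
                "anchor": self.anchor,
                "anchor_window": self.anchor_window,
                "atmosphere_fit_region": list(self.atmosphere_fit_region),
                "steps": list(self.steps),
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "PreprocessConfig":
        raw = yaml.safe_load(text) or {}
        known = {
            "crop_lo", "crop_hi", "anchor", "anchor_window",
            "atmosphere_fit_region", "steps",
        }
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "atmosphere_fit_region" in raw:
            raw["atmosphere_fit_region"] = tuple(raw["atmosphere_fit_region"])
        if "steps" in raw:
            raw["steps"] = tuple(raw["steps"])
        return cls(**raw)


# --------------------------------------------------------------------------
# Atmospheric correction


def _second_difference_rows(n: int, region_mask: np.ndarray) -> np.ndarray:
    """Indices i such that the second difference at i uses only in-region points."""
    idx = np.arange(1, n - 1)
    ok = region_mask[idx - 1] & region_mask[idx] & region_mask[idx + 1]
    return idx[ok]


def atmosphere_coefficients(
    absorbance: np.ndarray,
    grid: WavenumberGrid,
    references: list[Spectrum],
    fit_region: tuple[float, float],
) -> np.ndarray:
    """Least-squares coefficients minimizing the roughness (sum of squared
    second differences) of ``absorbance − Σ c_k·ref_k`` inside ``fit_region``.

    ``absorbance`` may be a single spectrum (n,) or a stack (..., n); one
    coefficient vector is returned per spectrum.
    """
    n = len(grid)
    mask = grid.window_mask(*fit_region)
    rows = _second_difference_rows(n, mask)
    if rows.size < len(references):
        raise RangeError("fit region too small for the atmospheric correction")
    R = np.stack([resample_to_grid(r, grid).absorbance for r in references], axis=1)
    D2R = R[rows - 1] - 2.0 * R[rows] + R[rows + 1]
    norms = np.linalg.norm(D2R, axis=0)
    if np.any(norms < 1e-12):
        raise DegeneracyError("a reference has no structure inside the fit region")
    a = np.asarray(absorbance, dtype=float)
    D2a = a[..., rows - 1] - 2.0 * a[..., rows] + a[..., rows + 1]
    coeffs, *_ = np.linalg.lstsq(D2R, D2a.reshape(-1, rows.size).T, rcond=None)
    return coeffs.T.reshape(a.shape[:-1] + (len(references),))


def correct_atmosphere(
    spectrum: Spectrum,
    references: list[Spectrum],
    fit_region: tuple[float, float] = (1300.0, 1800.0),
) -> Spectrum:
    """Subtract fitted gas-line references; smooth sample bands are preserved
    because the fit criterion is the roughness of the residual, which the
    sharp rotational-vibrational lines dominate.  With no references this is
    the identity."""
    if not references:
        return spectrum.copy()
    c = atmosphere_coefficients(spectrum.absorbance, spectrum.grid, references, fit_region)
    R = np.stack([resample_to_grid(r, spectrum.grid).absorbance for r in references], axis=1)
    corrected = spectrum.absorbance - R @ c
    return spectrum.copy(absorbance=corrected)


# --------------------------------------------------------------------------
# Crop


def crop(obj, lo: float, hi: float):
    """Restrict a Spectrum or cube to wavenumbers in the closed interval [lo, hi]."""
    grid = obj.grid
    mask = grid.window_mask(lo, hi)
    if not np.any(mask):
        raise RangeError(f"crop window [{lo}, {hi}] retains no grid points")
    new_grid = WavenumberGrid(grid.values[mask])
    if isinstance(obj, Spectrum):
        return Spectrum(new_grid, obj.absorbance[mask], obj.label)
    if isinstance(obj, HyperspectralCube):
        out = HyperspectralCube(
            pixel_size=obj.pixel_size,
            grid=new_grid,
            data=obj.data[:, :, mask],
            modality=obj.modality,
            provenance=dict(obj.provenance),
            mask=None if obj.mask is None else obj.mask.copy(),
        )
        return out
    raise TypeError(f"crop expects a Spectrum or HyperspectralCube, got {type(obj)}")


# --------------------------------------------------------------------------
# Rubberband baseline


def lower_hull_baseline(wn: np.ndarray, absorbance: np.ndarray) -> np.ndarray:
    """Lower convex hull of {(ν_i, a_i)} evaluated by linear interpolation
    between hull vertices (Andrew's monotone chain restricted to the lower
    chain; wavenumbers are already sorted ascending)."""
    n = wn.size
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep k only if it is strictly below the j->i chord
            if (wn[k] - wn[j]) * (absorbance[i] - absorbance[j]) - (
                wn[i] - wn[j]
            ) * (absorbance[k] - absorbance[j]) <= 0.0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wn, wn[hull], absorbance[hull])


def rubberband_baseline(spectrum: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Rubberband baseline correction.

    Returns ``(baseline, corrected)`` where the baseline is the lower convex
    hull of the spectrum and ``corrected = spectrum − baseline`` is
    non-negative, zero at hull vertices (in particular at both endpoints).
    """
    baseline = lower_hull_baseline(spectrum.grid.values, spectrum.absorbance)
    corrected = np.maximum(spectrum.absorbance - baseline, 0.0)
    return (
        spectrum.copy(absorbance=baseline, label=f"{spectrum.label} baseline"),
        spectrum.copy(absorbance=corrected),
    )


# --------------------------------------------------------------------------
# Normalization

NORMALIZATION_FLOOR = 1e-6


def anchor_window_max(
    absorbance: np.ndarray, grid: WavenumberGrid, anchor: float, window: float
) -> np.ndarray:
    mask = grid.window_mask(anchor - window, anchor + window)
    if not np.any(mask):  # window clipped off the grid entirely
        raise RangeError("anchor window lies outside the grid")
    return np.asarray(absorbance, dtype=float)[..., mask].max(axis=-1)


def normalize_to_peak(
    spectrum: Spectrum,
    anchor: float = 1370.0,
    window: float = 15.0,
    floor: float = NORMALIZATION_FLOOR,
) -> Spectrum:
    """Divide the spectrum by its maximum inside ``anchor ± window``."""
    peak = float(anchor_window_max(spectrum.absorbance, spectrum.grid, anchor, window))
    if peak <= floor:
        raise NormalizationError(
            f"anchor-window maximum {peak:g} at {anchor}±{window} cm⁻¹ is below the floor"
        )
    return spectrum.copy(absorbance=spectrum.absorbance / peak)


# --------------------------------------------------------------------------
# Cube pipeline


def preprocess_cube(
    cube: HyperspectralCube,
    config: PreprocessConfig = PreprocessConfig(),
    references: list[Spectrum] | None = None,
) -> HyperspectralCube:
    """Apply the enabled steps, in the configured order, to every pixel.

    Pixels whose anchor peak falls below the normalization floor (e.g. hypha
    on bare gold, where there is no cellulose anchor) are masked rather than
    zero-filled; the mask travels with the cube and is reported in provenance.
    """
    data = cube.data.copy()
    grid = cube.grid
    mask = np.zeros(data.shape[:2], dtype=bool) if cube.mask is None else cube.mask.copy()
    out = HyperspectralCube(
        pixel_size=cube.pixel_size,
        grid=grid,
        data=data,
        modality=cube.modality,
        provenance=dict(cube.provenance),
        mask=mask,
    )
    for step in config.steps:
        if step == "atmosphere":
            refs = references or []
            if refs:
                flat = out.data.reshape(-1, len(out.grid))
                c = atmosphere_coefficients(
                    flat, out.grid, refs, config.atmosphere_fit_region
                )
                R = np.stack(
                    [resample_to_grid(r, out.grid).absorbance for r in refs], axis=1
                )
                flat -= c @ R.T
                out.data = flat.reshape(out.data.shape)
                out.add_history(
                    "step=atmosphere;params=fit_region="
                    f"{config.atmosphere_fit_region};n_refs={len(refs)};"
                    f"mean_coeff={np.round(c.mean(axis=0), 6).tolist()}"
                )
            else:
                out.add_history("step=atmosphere;params=no references (identity)")
        elif step == "crop":
            cropped = crop(out, config.crop_lo, config.crop_hi)
            cropped.provenance = out.provenance
            cropped.mask = out.mask
            out = cropped
            out.add_history(f"step=crop;params=lo={config.crop_lo};hi={config.crop_hi}")
        elif step == "rubberband":
            wn = out.grid.values
            flat = out.data.reshape(-1, wn.size)
            for i in range(flat.shape[0]):
                flat[i] = np.maximum(flat[i] - lower_hull_baseline(wn, flat[i]), 0.0)
            out.data = flat.reshape(out.data.shape)
            out.add_history("step=rubberband;params=lower convex hull")
        elif step == "normalize":
            peaks = anchor_window_max(out.data, out.grid, config.anchor, config.anchor_window)
            bad = peaks <= NORMALIZATION_FLOOR
            out.mask = out.mask | bad
            safe = np.where(bad, 1.0, peaks)
            out.data = out.data / safe[:, :, None]
            out.add_history(
                f"step=normalize;params=anchor={config.anchor};window={config.anchor_window};"
                f"masked_pixels={int(bad.sum())}"
            )
            out.provenance["masked_pixels"] = str(int(out.mask.sum()))
    return out


# --------------------------------------------------------------------------
# Peak detection


def detect_peaks(
    spectrum: Spectrum, min_height: float = 0.05, window: float = 8.0
) -> list[tuple[float, float]]:
    """Local maxima above ``min_height`` × global max, separated by at least
    ``window`` cm⁻¹; centers refined by 3-point parabolic interpolation.
    Returns (center, height) pairs sorted by descending height."""
    a = spectrum.absorbance
    wn = spectrum.grid.values
    top = a.max()
    if top <= 0:
        return []
    step = float(np.median(np.diff(wn)))
    distance = max(1, int(round(window / step)))
    idx, props = find_peaks(a, height=min_height * top, distance=distance)
    peaks = []
    for i in idx:
        center = wn[i]
        height = a[i]
        if 0 < i < wn.size - 1:
            denom = a[i - 1] - 2.0 * a[i] + a[i + 1]
            if denom < 0:
                delta = 0.5 * (a[i - 1] - a[i + 1]) / denom
                center = wn[i] + delta * (wn[i + 1] - wn[i - 1]) / 2.0
                height = a[i] - 0.25 * (a[i - 1] - a[i + 1]) * delta
        peaks.append((float(center), float(height)))
    peaks.sort(key=lambda p: -p[1])
    return peaks
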