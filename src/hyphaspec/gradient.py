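"""Radial gradient analysis of the decomposition zone.

Radial cuts are drawn from the hyphal edge near the tip, pixels near the cuts
are selected, the selected normalized spectra are unmixed with two-component
MCR-ALS, and each pixel's contributions are related to its distance from the
hyphal midline.  A lowess trend and zone-wise straight-line fits quantify the
chemical gradient: the decomposition-signature contribution changes linearly
with distance inside the zone and is flat outside it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.ndimage import binary_dilation
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import (
    GeometryError,
    InsufficientSupportError,
    SelectionError,
    ValidationError,
)
from .geometry import segment_distance
from .segmentation import LABEL_HYPHA, LABEL_MASKED, ClusterMap, ZoneGeometry
from .spectral_core import HyperspectralCube, Spectrum, WavenumberGrid
from .unmixing import MixtureMatrix, UnmixingResult, simplisma_mcr

CO_WINDOW = (1600.0, 1700.0)


@dataclass
class RadialCutSet:
    """Rays fanning out from a point on the hyphal edge near the tip."""

    origin: tuple[float, float]          # µm
    directions: np.ndarray               # angles, radians
    max_length: float                    # µm (pre-clipping)
    selection_halfwidth: float           # µm
    endpoints: np.ndarray                # (n_cuts, 2) clipped ray ends, µm
    clipped: np.ndarray                  # bool per cut
    selected_pixels: list[tuple[int, int, float]] = field(default_factory=list)


def _clip_ray(origin, angle, max_length, width, height):
    """Longest t ≤ max_length keeping origin + t·dir inside [0,width]×[0,height]."""
    d = np.array([np.cos(angle), np.sin(angle)])
    t = max_length
    for coord, lo, hi in ((0, 0.0, width), (1, 0.0, height)):
        if d[coord] > 1e-12:
            t = min(t, (hi - origin[coord]) / d[coord])
        elif d[coord] < -1e-12:
            t = min(t, (lo - origin[coord]) / d[coord])
    return max(t, 0.0), t < max_length - 1e-9


def make_radial_cuts(
    cmap: ClusterMap,
    n_cuts: int = 6,
    fan_degrees: float = 150.0,
    max_length: float = 12.0,
    selection_halfwidth: float | None = None,
) -> RadialCutSet:
    """Rays from the hypha boundary pixel nearest the hyphal tip.

    The tip is the far end of the hypha cluster's principal axis; rays are
    spread evenly over ``fan_degrees`` centered on the outward axis direction.
    Rays reaching past the image edge are clipped and flagged.
    """
    if n_cuts < 1:
        raise ValidationError("need at least one cut")
    from .segmentation import measure_zone_geometry

    geometry = measure_zone_geometry(cmap)
    (x0, y0), (x1, y1) = geometry.midline_estimate
    tip = np.array([x1, y1])
    other = np.array([x0, y0])
    outward = tip - other
    norm = np.linalg.norm(outward)
    if norm == 0:
        raise GeometryError("degenerate midline; cannot orient cuts")
    outward /= norm

    ps = cmap.pixel_size
    hy_r, hy_c = np.nonzero(cmap.zone_mask(LABEL_HYPHA))
    centers = np.stack([(hy_c + 0.5) * ps, (hy_r + 0.5) * ps], axis=1)
    # boundary pixels: hypha pixels with at least one non-hypha 4-neighbour
    hymask = cmap.zone_mask(LABEL_HYPHA)
    padded = np.pad(hymask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = hymask & ~interior
    b_r, b_c = np.nonzero(boundary)
    if b_r.size == 0:
        b_r, b_c = hy_r, hy_c
    b_centers = np.stack([(b_c + 0.5) * ps, (b_r + 0.5) * ps], axis=1)
    origin = b_centers[np.argmin(np.linalg.norm(b_centers - tip, axis=1))]

    base = np.arctan2(outward[1], outward[0])
    if n_cuts == 1:
        angles = np.array([base])
    else:
        half = np.deg2rad(fan_degrees) / 2.0
        angles = base + np.linspace(-half, half, n_cuts)

    rows, cols = cmap.shape
    width, height = cols * ps, rows * ps
    lengths, clipped = zip(
        *(_clip_ray(origin, a, max_length, width, height) for a in angles)
    )
    endpoints = np.stack(
        [origin + t * np.array([np.cos(a), np.sin(a)]) for a, t in zip(angles, lengths)]
    )
    return RadialCutSet(
        origin=(float(origin[0]), float(origin[1])),
        directions=np.asarray(angles),
        max_length=max_length,
        selection_halfwidth=selection_halfwidth if selection_halfwidth is not None else ps,
        endpoints=endpoints,
        clipped=np.asarray(clipped, dtype=bool),
    )


def select_pixels_near_cuts(
    cuts: RadialCutSet, cube: HyperspectralCube, cmap: ClusterMap
) -> RadialCutSet:
    """Fill ``selected_pixels`` with (row, col, distance-to-midline µm).

    A pixel is selected when its center lies within ``selection_halfwidth``
    of at least one cut segment; masked and hypha-labeled pixels are excluded
    (the profile examines the decomposition zone, not the intracellular
    protein), duplicates (pixels near two rays) are counted once.  The
    distance annotation is the Euclidean distance from the pixel center to
    the hyphal midline segment (the gradient's distance coordinate), not the
    distance along the ray.
    """
    from .segmentation import measure_zone_geometry

    geometry = measure_zone_geometry(cmap)
    p0, p1 = geometry.midline_estimate
    x, y = cube.pixel_centers()
    origin = np.array(cuts.origin)
    near = np.zeros(cmap.shape, dtype=bool)
    for end in cuts.endpoints:
        d = segment_distance(x, y, tuple(origin), tuple(end))
        near |= d <= cuts.selection_halfwidth
    if cube.mask is not None:
        near &= ~cube.mask
    near &= cmap.labels != LABEL_MASKED
    # exclude the hypha plus a one-pixel guard ring: boundary pixels straddle
    # the cell wall and mix intracellular protein into the film spectra
    hypha_dilated = binary_dilation(cmap.labels == LABEL_HYPHA, np.ones((3, 3), bool))
    near &= ~hypha_dilated
    rr, cc = np.nonzero(near)
    if rr.size == 0:
        raise SelectionError("no pixels fall within the selection halfwidth of any cut")
    dist = segment_distance(x[rr, cc], y[rr, cc], p0, p1)
    cuts.selected_pixels = [
        (int(r), int(c), float(d)) for r, c, d in zip(rr, cc, dist)
    ]
    return cuts


@dataclass
class ZoneFit:
    slope_in: float
    r2_in: float
    slope_out: float
    n_in: int
    n_out: int

    def to_json(self) -> str:
        return json.dumps(
            {"slope_in": self.slope_in, "r2_in": self.r2_in, "slope_out": self.slope_out}
        )


@dataclass
class GradientProfile:
    distances: np.ndarray                    # per-pixel distance to midline, µm
    contributions: np.ndarray                # n×2 MCR contributions
    components: list[Spectrum]
    decomposition_index: int                 # column carrying the C=O signature
    pixel_index: np.ndarray
    unmixing: UnmixingResult
    lowess_trend: dict[int, np.ndarray] | None = None   # component -> (x, yhat)
    zone_fit: ZoneFit | None = None

    @property
    def decomposition_contribution(self) -> np.ndarray:
        return self.contributions[:, self.decomposition_index]


def two_component_profile(
    cube: HyperspectralCube, cuts: RadialCutSet, alpha: float = 0.05
) -> GradientProfile:
    """Two-component MCR-ALS of the selected spectra vs distance.

    The decomposition-signature component is the one with the greater mean
    spectral amplitude over 1600–1700 cm⁻¹ (the C=O region of oxidized
    cellulose).
    """
    if len(cuts.selected_pixels) < 10:
        raise InsufficientSupportError("need at least 10 selected pixels")
    rows = np.array([p[0] for p in cuts.selected_pixels])
    cols = np.array([p[1] for p in cuts.selected_pixels])
    dist = np.array([p[2] for p in cuts.selected_pixels])
    D = cube.data[rows, cols]
    matrix = MixtureMatrix(
        D=D, pixel_index=np.stack([rows, cols], axis=1), grid=cube.grid
    )
    result = simplisma_mcr(matrix, k=2, alpha=alpha)
    window = cube.grid.window_mask(*CO_WINDOW)
    co_amp = result.S[window].mean(axis=0)
    decomp_idx = int(np.argmax(co_amp))
    components = [
        Spectrum(cube.grid, result.S[:, j].copy(),
                 "decomposition signature" if j == decomp_idx else "cellulose-like")
        for j in range(2)
    ]
    return GradientProfile(
        distances=dist,
        contributions=result.C,
        components=components,
        decomposition_index=decomp_idx,
        pixel_index=matrix.pixel_index,
        unmixing=result,
    )


def lowess_trend(profile: GradientProfile, frac: float = 0.3) -> GradientProfile:
    """Robust lowess (tricube weights, 2 robustifying iterations) of each
    contribution against distance, evaluated at the sorted unique distances."""
    if not 0.0 < frac <= 1.0:
        raise ValidationError("frac must be in (0, 1]")
    if profile.distances.size < 10:
        raise InsufficientSupportError("need at least 10 points for a trend")
    trends: dict[int, np.ndarray] = {}
    for j in range(profile.contributions.shape[1]):
        fitted = _sm_lowess(
            profile.contributions[:, j], profile.distances, frac=frac, it=2,
            return_sorted=True,
        )
        x, inv = np.unique(fitted[:, 0], return_inverse=True)
        yhat = np.zeros_like(x)
        counts = np.bincount(inv)
        np.add.at(yhat, inv, fitted[:, 1])
        yhat /= counts
        trends[j] = np.stack([x, yhat])
    profile.lowess_trend = trends
    return profile


def zone_linearity(
    profile: GradientProfile, geometry: ZoneGeometry, boundary_buffer: float = 0.0
) -> ZoneFit:
    """Straight-line fits of the decomposition-signature contribution.

    In-zone: distances within [hypha_width/2, hypha_width/2 + halo_extent]
    (slope and R²); out-of-zone: distances beyond the halo (slope only, to
    verify flatness).  The measured zone geometry supplies the boundaries.
    ``boundary_buffer`` (µm, typically one pixel) excludes a transition band
    at the outer boundary from both fits: the boundary is only known to pixel
    precision and pixels straddling it mix the two zones.
    """
    inner = geometry.hypha_width / 2.0
    outer = inner + geometry.halo_extent
    d = profile.distances
    c = profile.decomposition_contribution
    in_mask = (d >= inner) & (d <= outer - boundary_buffer)
    out_mask = d > outer + boundary_buffer
    if in_mask.sum() < 5 or out_mask.sum() < 5:
        raise InsufficientSupportError(
            f"too few points for zone fits (in={int(in_mask.sum())}, out={int(out_mask.sum())})"
        )
    fit_in = stats.linregress(d[in_mask], c[in_mask])
    fit_out = stats.linregress(d[out_mask], c[out_mask])
    zone_fit = ZoneFit(
        slope_in=float(fit_in.slope),
        r2_in=float(fit_in.rvalue**2),
        slope_out=float(fit_out.slope),
        n_in=int(in_mask.sum()),
        n_out=int(out_mask.sum()),
    )
    profile.zone_fit = zone_fit
    return zone_fit
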