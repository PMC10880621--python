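"""k-means zone segmentation and zone-geometry measurement.

Pixels are clustered on their MCR-ALS contribution vectors (standardized per
component) with k-means, k = 3.  Clusters are given semantic zone labels by
ranking their mean normalized absorbance over the amide/carbonyl window
1500–1700 cm⁻¹: highest → hypha, middle → decomposition zone, lowest →
background.  Geometry (hypha width, decomposition-halo extent) is measured in
µm from cross-sections perpendicular to the hypha's principal axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .errors import (
    AmbiguousLabelingError,
    DegeneracyError,
    InsufficientSupportError,
    ValidationError,
)
from .geometry import principal_axis
from .spectral_core import HyperspectralCube, Spectrum
from .synthetic_scene import LABEL_BACKGROUND, LABEL_DECOMPOSITION, LABEL_HYPHA
from .unmixing import MixtureMatrix

LABEL_MASKED = -1
AMIDE_WINDOW = (1500.0, 1700.0)
ZONE_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_DECOMPOSITION: "decomposition",
    LABEL_HYPHA: "hypha",
}
# Fig 2C/3C palette: blue background, orange decomposition, green hypha.
ZONE_COLORS = {
    LABEL_MASKED: (0.85, 0.85, 0.85),
    LABEL_BACKGROUND: (0.19, 0.42, 0.76),
    LABEL_DECOMPOSITION: (0.95, 0.55, 0.10),
    LABEL_HYPHA: (0.22, 0.63, 0.26),
}


@dataclass
class ClusterMap:
    """Semantic zone map plus per-zone mean ± SD spectra."""

    labels: np.ndarray                     # rows×cols in {-1, 0, 1, 2}
    pixel_size: float
    mean_spectra: dict[int, Spectrum]
    sd_spectra: dict[int, Spectrum]
    seed: int
    zones_present: tuple[int, ...]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def zone_mask(self, zone: int) -> np.ndarray:
        return self.labels == zone

    def to_rgb(self) -> np.ndarray:
        rgb = np.zeros(self.labels.shape + (3,))
        for zone, color in ZONE_COLORS.items():
            rgb[self.labels == zone] = color
        return rgb


def cluster_contributions(
    C: np.ndarray, k: int = 3, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """k-means on contribution rows standardized per column to unit variance.

    Uses the best of ``n_init`` restarts by within-cluster sum of squares;
    deterministic given ``seed``.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] < k:
        raise DegeneracyError("need at least k contribution rows")
    if np.unique(C, axis=0).shape[0] < k:
        raise DegeneracyError(f"fewer than k={k} distinct contribution rows")
    sd = C.std(axis=0)
    Z = C / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(Z)


def assign_zone_labels(
    labels: np.ndarray,
    mixture: MixtureMatrix,
    cube: HyperspectralCube,
    seed: int = 0,
) -> ClusterMap:
    """Map raw cluster indices to semantic zones.

    Ranking is by mean normalized absorbance over 1500–1700 cm⁻¹ (amide /
    carbonyl region): highest → hypha, middle → decomposition, lowest →
    background.  With only two clusters present (e.g. a hypha on bare gold,
    where all film pixels are masked) the labels reduce to hypha and
    background, and the absent decomposition zone is flagged in provenance.
    """
    labels = np.asarray(labels)
    cluster_ids = np.unique(labels)
    n_clusters = cluster_ids.size
    if n_clusters not in (2, 3):
        raise ValidationError(f"expected 2 or 3 clusters, got {n_clusters}")

    window = cube.grid.window_mask(*AMIDE_WINDOW)
    amide_means = {}
    for cid in cluster_ids:
        rows = labels == cid
        amide_means[cid] = float(cube.data[tuple(mixture.pixel_index[rows].T)][:, window].mean())

    ranked = sorted(cluster_ids, key=lambda cid: amide_means[cid])
    gaps = np.diff([amide_means[cid] for cid in ranked])
    if np.any(gaps < 1e-9):
        raise AmbiguousLabelingError("amide-region ranking is tied; cannot assign zones")
    if n_clusters == 3:
        semantic = {ranked[0]: LABEL_BACKGROUND, ranked[1]: LABEL_DECOMPOSITION,
                    ranked[2]: LABEL_HYPHA}
        zones_present = (LABEL_BACKGROUND, LABEL_DECOMPOSITION, LABEL_HYPHA)
    else:
        semantic = {ranked[0]: LABEL_BACKGROUND, ranked[1]: LABEL_HYPHA}
        zones_present = (LABEL_BACKGROUND, LABEL_HYPHA)

    label_img = np.full((cube.rows, cube.cols), LABEL_MASKED, dtype=int)
    for cid, zone in semantic.items():
        rows = mixture.pixel_index[labels == cid]
        label_img[rows[:, 0], rows[:, 1]] = zone

    mean_spectra: dict[int, Spectrum] = {}
    sd_spectra: dict[int, Spectrum] = {}
    for zone in zones_present:
        mask = label_img == zone
        pix = cube.data[mask]
        name = ZONE_NAMES[zone]
        mean_spectra[zone] = Spectrum(cube.grid, pix.mean(axis=0), f"{name} mean")
        sd_spectra[zone] = Spectrum(cube.grid, pix.std(axis=0), f"{name} sd")

    provenance = {
        "amide_window": f"{AMIDE_WINDOW[0]}-{AMIDE_WINDOW[1]}",
        "amide_means": json.dumps({ZONE_NAMES[semantic[c]]: amide_means[c] for c in cluster_ids}),
    }
    if n_clusters == 2:
        provenance["decomposition_zone"] = "absent (two-cluster scene)"
    return ClusterMap(
        labels=label_img,
        pixel_size=cube.pixel_size,
        mean_spectra=mean_spectra,
        sd_spectra=sd_spectra,
        seed=seed,
        zones_present=zones_present,
        provenance=provenance,
    )


@dataclass
class ZoneGeometry:
    hypha_width: float                     # µm
    halo_extent: float                     # µm from hyphal edge, both sides averaged
    midline_estimate: tuple[tuple[float, float], tuple[float, float]]
    station_widths: list[float]
    station_halos: dict[str, list[float]]

    def to_json(self) -> str:
        return json.dumps(
            {"hypha_width_um": self.hypha_width, "halo_extent_um": self.halo_extent}
        )


def measure_zone_geometry(cmap: ClusterMap) -> ZoneGeometry:
    """Measure hypha width and decomposition-halo extent in µm.

    The midline is the principal axis of hypha-labeled pixel centers.  At
    stations spaced one pixel apart along the axis, the perpendicular
    cross-section is sampled at pixel-size steps: the hypha width is the run
    length of hypha labels around the axis, and the halo extent on each side
    is the distance from the hypha run's outer edge to the *last*
    decomposition-labeled sample.  Medians over stations are used (robust to
    the ragged tip), and the two side medians are averaged.
    """
    ps = cmap.pixel_size
    hy_r, hy_c = np.nonzero(cmap.zone_mask(LABEL_HYPHA))
    if hy_r.size < 4:
        raise InsufficientSupportError(
            f"hypha cluster has {hy_r.size} pixels; need at least 4"
        )
    centers = np.stack([(hy_c + 0.5) * ps, (hy_r + 0.5) * ps], axis=1)  # (x, y) µm
    center, direction = principal_axis(centers)
    normal = np.array([-direction[1], direction[0]])

    proj = (centers - center) @ direction
    t_lo, t_hi = proj.min(), proj.max()

    rows, cols = cmap.shape
    max_offset = int(np.ceil(np.hypot(rows, cols)))

    def label_at(point: np.ndarray) -> int:
        c = int(np.floor(point[0] / ps))
        r = int(np.floor(point[1] / ps))
        if 0 <= r < rows and 0 <= c < cols:
            return int(cmap.labels[r, c])
        return LABEL_MASKED

    widths: list[float] = []
    halos: dict[str, list[float]] = {"side_a": [], "side_b": []}
    n_stations = max(1, int(np.floor((t_hi - t_lo) / ps)) + 1)
    for s in range(n_stations):
        station = center + (t_lo + s * ps) * direction
        offsets = np.arange(-max_offset, max_offset + 1)
        samples = np.array([label_at(station + j * ps * normal) for j in offsets])
        hy_idx = np.flatnonzero(samples == LABEL_HYPHA)
        if hy_idx.size == 0:
            continue
        # contiguous hypha run containing the sample nearest the axis
        anchor = hy_idx[np.argmin(np.abs(offsets[hy_idx]))]
        lo = anchor
        while lo - 1 >= 0 and samples[lo - 1] == LABEL_HYPHA:
            lo -= 1
        hi = anchor
        while hi + 1 < samples.size and samples[hi + 1] == LABEL_HYPHA:
            hi += 1
        widths.append((hi - lo + 1) * ps)
        for side, (edge, sl) in zip(
            ("side_a", "side_b"),
            ((lo, slice(lo - 1, None, -1)), (hi, slice(hi + 1, None))),
        ):
            beyond = samples[sl]
            decomp = np.flatnonzero(beyond == LABEL_DECOMPOSITION)
            halos[side].append(float((decomp[-1] + 1) * ps) if decomp.size else 0.0)

    if not widths:
        raise InsufficientSupportError("no cross-section intersected the hypha cluster")
    width = float(np.median(widths))
    # the pixel-center span includes the rounded tip caps; the midline of a
    # capsule is the axis span shrunk by half the width at each end
    half = width / 2.0
    if t_hi - t_lo > 2.0 * half:
        m_lo, m_hi = t_lo + half, t_hi - half
    else:
        m_lo, m_hi = t_lo, t_hi
    p0 = tuple(center + m_lo * direction)
    p1 = tuple(center + m_hi * direction)
    side_medians = [
        float(np.median(vals)) if vals else 0.0 for vals in halos.values()
    ]
    halo = float(np.mean(side_medians))
    return ZoneGeometry(
        hypha_width=width,
        halo_extent=halo,
        midline_estimate=(p0, p1),
        station_widths=widths,
        station_halos=halos,
    )
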