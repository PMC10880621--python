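"""Ground-truth pure-component spectra and spatial scenes.

The generator emulates the study system: a thin regenerated-cellulose film on
gold, a single fungal hypha (intracellular protein, amide I/II bands at
1650/1550 cm⁻¹) and a surrounding decomposition zone in which the film is
progressively oxidized.  Following the measured radial trend, the degree of
oxidation rises linearly with distance from the hyphal edge, reaching its
maximum at the outer zone boundary (``halo_extent``) and dropping to zero in
the unaltered background beyond — the decomposition zone has a definite
chemical boundary, inside which alteration grows with distance from the
hypha.

Everything in this module is deterministic: scenes are pure functions of
their geometry parameters, and all invented band parameters are recorded in
the library so tests can assert against provenance rather than duplicated
constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, RangeError, ValidationError
from .geometry import segment_distance
from .spectral_core import HyperspectralCube, Spectrum, WavenumberGrid

COMPONENT_NAMES = (
    "cellulose",
    "cellulose_acetate",
    "oxidized_cellulose",
    "protein",
    "water_vapor",
)

LABEL_BACKGROUND = 0
LABEL_DECOMPOSITION = 1
LABEL_HYPHA = 2


@dataclass(frozen=True)
class Band:
    """A single absorption band: center/fwhm in cm⁻¹, height in absorbance."""

    center: float
    fwhm: float
    height: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValidationError("band fwhm must be > 0")
        if self.height < 0:
            raise ValidationError("band height must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValidationError(f"unknown band shape {self.shape!r}")


_LN2x4 = 4.0 * np.log(2.0)


def build_pure_spectrum(bands: list[Band], grid: WavenumberGrid, label: str = "") -> Spectrum:
    """Sum of band profiles on ``grid``.

    Gaussian: ``h * exp(-4 ln2 ((v - c)/fwhm)^2)``;
    Lorentzian: ``h / (1 + (2 (v - c)/fwhm)^2)``.
    An empty band list yields the zero spectrum.
    """
    v = grid.values
    a = np.zeros_like(v)
    for b in bands:
        u = (v - b.center) / b.fwhm
        if b.shape == "gaussian":
            a += b.height * np.exp(-_LN2x4 * u * u)
        else:
            a += b.height / (1.0 + 4.0 * u * u)
    return Spectrum(grid, a, label)


# --------------------------------------------------------------------------
# Default band lists (emulation parameters; the named positions 1742, 1650,
# 1550, 1370, 1219, 1160 cm⁻¹ are the literature band assignments, the rest
# shape the spectra realistically).

_CELLULOSE_BANDS = [
    Band(1035.0, 60.0, 1.00),   # C-O stretch, strongest band of the film
    Band(1060.0, 40.0, 0.90),
    Band(985.0, 40.0, 0.55),
    Band(1160.0, 24.0, 0.45),   # C-O-C ether stretch
    Band(1315.0, 24.0, 0.28),
    Band(1370.0, 22.0, 0.38),   # CH bend; the normalization anchor
    Band(1430.0, 28.0, 0.24),
    Band(895.0, 18.0, 0.12),
]

_ACETATE_BANDS = [
    Band(1742.0, 30.0, 0.55),   # ester C=O
    Band(1219.0, 28.0, 0.40),   # ester C-O
]

# Oxidation: carbohydrate-region (1100–950 cm⁻¹) bands attenuated, plus a
# carbonyl/carboxylate band inside 1700–1600 cm⁻¹.
_OXIDATION_CARB_SCALE = 0.55
_OXIDATION_CO_BAND = Band(1625.0, 55.0, 0.50)

_PROTEIN_BANDS = [
    Band(1650.0, 45.0, 1.00),   # amide I
    Band(1550.0, 40.0, 0.80),   # amide II
    Band(1450.0, 30.0, 0.12),
    Band(1240.0, 40.0, 0.05),   # amide III tail, kept < 5% of max
]

# Narrow rotational-vibrational water-vapor lines, all within 1300–1800 cm⁻¹.
_WATER_VAPOR_LINES = [
    (1326, 0.25), (1340, 0.45), (1356, 0.70), (1374, 0.40), (1396, 0.90),
    (1418, 0.55), (1437, 0.30), (1458, 0.85), (1476, 0.50), (1496, 0.65),
    (1508, 0.40), (1522, 0.70), (1540, 1.00), (1560, 0.60), (1576, 0.80),
    (1594, 0.50), (1616, 0.90), (1636, 0.45), (1653, 0.70), (1670, 0.35),
    (1684, 0.60), (1700, 0.40), (1717, 0.75), (1734, 0.30), (1750, 0.55),
    (1772, 0.35), (1790, 0.20),
]
_WATER_VAPOR_FWHM = 3.0


def _water_vapor_bands() -> list[Band]:
    return [Band(float(c), _WATER_VAPOR_FWHM, h) for c, h in _WATER_VAPOR_LINES]


def _oxidized_bands() -> list[Band]:
    bands = []
    for b in _CELLULOSE_BANDS:
        if 950.0 <= b.center <= 1100.0:
            bands.append(Band(b.center, b.fwhm, b.height * _OXIDATION_CARB_SCALE, b.shape))
        else:
            bands.append(b)
    bands.append(_OXIDATION_CO_BAND)
    return bands


@dataclass
class ComponentLibrary:
    """Named pure-component spectra on a shared grid.

    ``band_lists`` records the generating band parameters so that tests and
    provenance can refer to them rather than to hard-coded duplicates.
    """

    grid: WavenumberGrid
    spectra: dict[str, Spectrum]
    band_lists: dict[str, list[Band]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(COMPONENT_NAMES) - set(self.spectra)
        if missing:
            raise ValidationError(f"library missing components: {sorted(missing)}")
        for name, s in self.spectra.items():
            if np.any(s.absorbance < 0):
                raise ValidationError(f"component {name!r} has negative absorbance")

    def __getitem__(self, name: str) -> Spectrum:
        return self.spectra[name]

    def provenance_json(self) -> str:
        return json.dumps(
            {
                name: [
                    {"center": b.center, "fwhm": b.fwhm, "height": b.height, "shape": b.shape}
                    for b in bands
                ]
                for name, bands in self.band_lists.items()
            }
        )


def default_component_library(grid: WavenumberGrid) -> ComponentLibrary:
    """The five pure components used by scenes and the instrument model.

    Requires a grid spanning at least 900–1800 cm⁻¹ so that all named band
    positions are representable.
    """
    if grid.lo > 900.0 or grid.hi < 1800.0:
        raise RangeError(
            f"grid [{grid.lo}, {grid.hi}] must span at least 900–1800 cm⁻¹"
        )
    band_lists = {
        "cellulose": list(_CELLULOSE_BANDS),
        "cellulose_acetate": list(_CELLULOSE_BANDS) + list(_ACETATE_BANDS),
        "oxidized_cellulose": _oxidized_bands(),
        "protein": list(_PROTEIN_BANDS),
        "water_vapor": _water_vapor_bands(),
    }
    spectra = {
        name: build_pure_spectrum(bands, grid, label=name)
        for name, bands in band_lists.items()
    }
    return ComponentLibrary(grid=grid, spectra=spectra, band_lists=band_lists)


def simulate_deacetylation(library: ComponentLibrary, residual_fraction: float) -> Spectrum:
    """Film spectrum after (partial) removal of acetate side chains.

    ``residual_fraction`` = 0 is complete deacetylation (pure cellulose),
    1 is untreated cellulose acetate.
    """
    if not 0.0 <= residual_fraction <= 1.0:
        raise ValidationError(f"residual_fraction must be in [0, 1], got {residual_fraction}")
    cell = library["cellulose"].absorbance
    acet = library["cellulose_acetate"].absorbance
    return Spectrum(
        library.grid,
        cell + residual_fraction * (acet - cell),
        label=f"deacetylated(residual={residual_fraction:g})",
    )


# --------------------------------------------------------------------------
# Scenes


@dataclass
class SceneDefinition:
    """Ground-truth concentration maps on a fine spatial grid.

    ``concentration_maps`` holds per-component fine-grid maps (rows×cols,
    row-major, y down, in units of relative concentration).  ``oxidation_degree``
    and ``hypha_mask`` are kept alongside for validation and for scoring
    segmentations against ground truth.
    """

    extent: tuple[float, float]          # (width, height) µm
    fine_step: float                     # µm
    hypha_midline: tuple[tuple[float, float], tuple[float, float]]
    hypha_width: float                   # µm
    halo_extent: float                   # µm from hyphal edge to zone boundary
    oxidation_max: float                 # degree of conversion at the boundary
    protein_density: float
    substrate: str                       # cellulose_film | bare_gold
    hypha_opacity: float                 # fraction of film signal blocked by the hypha
    concentration_maps: dict[str, np.ndarray]
    hypha_mask: np.ndarray
    oxidation_degree: np.ndarray
    edge_distance: np.ndarray            # distance to hyphal edge (µm, <0 inside)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.hypha_mask.shape

    def zone_labels(self) -> np.ndarray:
        """Ground-truth zone map: 0 background, 1 decomposition, 2 hypha."""
        labels = np.full(self.shape, LABEL_BACKGROUND, dtype=int)
        labels[self.oxidation_degree > 0] = LABEL_DECOMPOSITION
        labels[self.hypha_mask] = LABEL_HYPHA
        return labels

    def fine_centers(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.shape
        x = (np.arange(cols) + 0.5) * self.fine_step
        y = (np.arange(rows) + 0.5) * self.fine_step
        return np.meshgrid(x, y)


def oxidation_profile(
    edge_distance: np.ndarray, halo_extent: float, oxidation_max: float
) -> np.ndarray:
    """Degree of oxidation as a function of distance from the hyphal edge.

    Zero at the edge, rising linearly to ``oxidation_max`` at the outer zone
    boundary, and zero beyond it (sharp boundary; the background film is
    unaltered).  Inside the hypha (negative distance) the film is unoxidized.
    """
    e = np.asarray(edge_distance, dtype=float)
    if halo_extent <= 0:
        return np.zeros_like(e)
    degree = oxidation_max * np.clip(e, 0.0, None) / halo_extent
    degree[e >= halo_extent] = 0.0
    degree[e < 0] = 0.0
    return degree


def build_scene(
    extent: tuple[float, float] = (147.2, 147.2),
    fine_step: float = 0.1,
    hypha_midline: tuple[tuple[float, float], tuple[float, float]] = ((61.67, 73.73), (85.67, 73.73)),
    hypha_width: float = 4.6,
    halo_extent: float = 6.3,
    oxidation_max: float = 0.6,
    protein_density: float = 1.0,
    substrate: str = "cellulose_film",
    hypha_opacity: float = 0.7,
) -> SceneDefinition:
    """Compute the ground-truth concentration maps for a single-hypha scene."""
    if fine_step > 0.25:
        raise ValidationError("fine_step must be <= 0.25 µm to resolve the PSF")
    if substrate not in ("cellulose_film", "bare_gold"):
        raise ValidationError(f"unknown substrate {substrate!r}")
    width, height = extent
    reach = hypha_width / 2.0 + halo_extent
    for px, py in hypha_midline:
        if px - reach < 0 or px + reach > width or py - reach < 0 or py + reach > height:
            raise GeometryError(
                "hypha plus decomposition halo does not fit inside the scene extent"
            )

    rows = int(round(height / fine_step))
    cols = int(round(width / fine_step))
    x = (np.arange(cols) + 0.5) * fine_step
    y = (np.arange(rows) + 0.5) * fine_step
    xx, yy = np.meshgrid(x, y)

    d_mid = segment_distance(xx, yy, *hypha_midline)
    edge = d_mid - hypha_width / 2.0
    hypha = edge <= 0.0
    degree = oxidation_profile(edge, halo_extent, oxidation_max)

    maps = {name: np.zeros((rows, cols)) for name in COMPONENT_NAMES}
    maps["protein"][hypha] = protein_density
    if substrate == "cellulose_film":
        film = np.ones((rows, cols))
        film[hypha] = 1.0 - hypha_opacity
        maps["cellulose"] = film * (1.0 - degree)
        maps["oxidized_cellulose"] = film * degree

    return SceneDefinition(
        extent=extent,
        fine_step=fine_step,
        hypha_midline=hypha_midline,
        hypha_width=hypha_width,
        halo_extent=halo_extent,
        oxidation_max=oxidation_max,
        protein_density=protein_density,
        substrate=substrate,
        hypha_opacity=hypha_opacity,
        concentration_maps=maps,
        hypha_mask=hypha,
        oxidation_degree=degree,
        edge_distance=edge,
        provenance={
            "extent": f"{width}x{height}",
            "fine_step": str(fine_step),
            "hypha_width_um": str(hypha_width),
            "halo_extent_um": str(halo_extent),
            "oxidation_max": str(oxidation_max),
            "substrate": substrate,
        },
    )


PRESET_NAMES = ("fig2_conventional", "fig3_optir", "fig5_gold")


def preset_scene(name: str):
    """Named scene + modality pairs mirroring the study's three imaging runs.

    ``fig2_conventional`` and ``fig3_optir`` share a single ground-truth scene
    (4.6 µm hypha, 6.3 µm decomposition halo) viewed through the two
    instruments; ``fig5_gold`` is a hypha on bare gold viewed with O-PTIR.
    Returns ``(SceneDefinition, ModalityConfig)``.
    """
    from .instrument_sim import modality_preset

    if name in ("fig2_conventional", "fig3_optir"):
        scene = build_scene()
        if name == "fig2_conventional":
            # full FPA field of view
            modality = modality_preset("conventional")
        else:
            # O-PTIR images a small rectangle of the conventional field,
            # centered on the hypha
            modality = modality_preset("optir", fov_um=(49.6, 53.6, 97.6, 93.6))
    elif name == "fig5_gold":
        scene = build_scene(
            extent=(20.0, 16.0),
            hypha_midline=((5.07, 8.13), (15.07, 8.13)),
            halo_extent=0.0,
            oxidation_max=0.0,
            substrate="bare_gold",
        )
        modality = modality_preset("optir")
    else:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    scene.provenance["preset"] = name
    return scene, modality


def scene_to_cube(
    scene: SceneDefinition,
    library: ComponentLibrary,
    grid: WavenumberGrid,
    step: float | None = None,
) -> HyperspectralCube:
    """Render the noiseless ground truth as a cube.

    ``step`` (µm, an integer multiple of the fine step) block-averages the
    concentration maps before rendering; by default the fine grid is used
    directly, which for large scenes can be very memory-hungry.
    """
    from .spectral_core import resample_to_grid

    comp_names = [n for n in COMPONENT_NAMES if np.any(scene.concentration_maps[n] != 0)]
    if not comp_names:
        comp_names = ["cellulose"]
    maps = [scene.concentration_maps[n] for n in comp_names]
    pixel_size = scene.fine_step
    if step is not None:
        factor = int(round(step / scene.fine_step))
        if factor < 1 or abs(factor * scene.fine_step - step) > 1e-9:
            raise ValidationError("step must be an integer multiple of fine_step")
        if factor > 1:
            rows = (maps[0].shape[0] // factor) * factor
            cols = (maps[0].shape[1] // factor) * factor
            maps = [
                m[:rows, :cols]
                .reshape(rows // factor, factor, cols // factor, factor)
                .mean(axis=(1, 3))
                for m in maps
            ]
            pixel_size = factor * scene.fine_step
    S = np.stack(
        [resample_to_grid(library[n], grid).absorbance for n in comp_names], axis=1
    )
    conc = np.stack(maps, axis=-1)
    data = conc @ S.T
    cube = HyperspectralCube(
        pixel_size=pixel_size,
        grid=grid,
        data=data,
        modality="ground_truth",
        provenance=dict(scene.provenance),
    )
    cube.add_history(f"rendered ground-truth scene (pixel {pixel_size} um)")
    return cube
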