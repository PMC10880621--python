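"""Instrument models: diffraction-limited blurring, pixel sampling, baseline
drift, atmospheric lines, and detector noise.

Two modalities are modelled.  Conventional IR microspectroscopy has a
wavenumber-dependent point spread function (Rayleigh limit of the IR light
itself, 16.9 µm at 900 cm⁻¹ to 8.5 µm at 1800 cm⁻¹ for NA 0.4) sampled on
2.3 µm pixels with 1024 co-added scans.  O-PTIR reads IR absorption through a
532 nm probe laser, so its PSF is set by the visible spot (416 nm at NA 0.78,
constant across the IR range) sampled on 0.5 µm pixels with 3 co-added scans.

The PSF is modelled as an isotropic Gaussian whose FWHM equals the Rayleigh
resolution; convolution uses reflecting boundaries so scene edges are not
darkened.  Detector pixels average the blurred fine-grid samples whose
centers fall inside the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, ValidationError
from .spectral_core import HyperspectralCube, Spectrum, WavenumberGrid, resample_to_grid
from .synthetic_scene import (
    COMPONENT_NAMES,
    ComponentLibrary,
    SceneDefinition,
    _water_vapor_bands,
    build_pure_spectrum,
    default_component_library,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ModalityConfig:
    """Acquisition parameters of one instrument.

    ``noise_sd_single_scan`` is the per-channel absorbance noise of a single
    scan; co-adding n scans divides it by √n.  ``probe_wavelength`` (nm) is
    only meaningful for O-PTIR.  ``fov_um`` optionally restricts the imaged
    region to a rectangle (x0, y0, x1, y1) of the scene, the way an O-PTIR
    raster covers a small window of the conventional field of view.
    """

    name: str
    numerical_aperture: float
    pixel_size: float                 # µm
    n_coadded_scans: int
    probe_wavelength: float | None = None  # nm
    noise_sd_single_scan: float = 0.02
    baseline_drift_amplitude: float = 0.03
    atmosphere_strength: float = 0.2
    rng_seed: int = 0
    fov_um: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValidationError("numerical aperture must be in (0, 1)")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.n_coadded_scans < 1:
            raise ValidationError("n_coadded_scans must be >= 1")
        if self.name == "optir" and self.probe_wavelength is None:
            raise ValidationError("optir modality requires a probe wavelength")


_PRESETS = {
    "conventional": ModalityConfig(
        name="conventional",
        numerical_aperture=0.4,
        pixel_size=2.3,
        n_coadded_scans=1024,
    ),
    "optir": ModalityConfig(
        name="optir",
        numerical_aperture=0.78,
        pixel_size=0.5,
        n_coadded_scans=3,
        probe_wavelength=532.0,
    ),
}


def modality_preset(name: str, **overrides) -> ModalityConfig:
    """Named acquisition presets: ``conventional`` (NA 0.4, 2.3 µm pixels,
    1024 scans) and ``optir`` (NA 0.78, 532 nm probe, 0.5 µm pixels, 3 scans)."""
    try:
        preset = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown modality {name!r}; choose from {tuple(_PRESETS)}") from None
    return replace(preset, **overrides) if overrides else preset


def rayleigh_resolution(wavelength: float, numerical_aperture: float) -> float:
    """Diffraction-limited resolution 0.61·λ/NA, in the units of ``wavelength``."""
    if wavelength <= 0 or not 0.0 < numerical_aperture <= 1.0:
        raise ValidationError("wavelength must be > 0 and NA in (0, 1]")
    return 0.61 * wavelength / numerical_aperture


def psf_width(modality: ModalityConfig, wavenumber: float) -> float:
    """PSF FWHM in µm at the given wavenumber.

    Conventional: Rayleigh limit of the IR wavelength (10⁴/ν µm).
    O-PTIR: Rayleigh limit of the visible probe, independent of wavenumber.
    """
    if modality.name == "optir":
        return rayleigh_resolution(modality.probe_wavelength, modality.numerical_aperture) / 1000.0
    if wavenumber <= 0:
        raise ValidationError("wavenumber must be > 0")
    return rayleigh_resolution(1.0e4 / wavenumber, modality.numerical_aperture)


def simulate_atmospheric_reference(
    modality: ModalityConfig, grid: WavenumberGrid, library: ComponentLibrary | None = None
) -> Spectrum:
    """The noise-free water-vapor 'blank' used by the atmospheric correction.

    Identical across seeds and modalities; built from the generator's line
    list (or taken from ``library`` when given).
    """
    if library is not None:
        return resample_to_grid(library["water_vapor"], grid).copy(label="water_vapor_reference")
    return build_pure_spectrum(_water_vapor_bands(), grid, label="water_vapor_reference")


def _bin_map(fine: np.ndarray, factor: int) -> np.ndarray:
    """Block-average ``fine`` by ``factor``; trailing remainder rows/cols are
    dropped (the detector raster does not cover them)."""
    rows = (fine.shape[0] // factor) * factor
    cols = (fine.shape[1] // factor) * factor
    trimmed = fine[:rows, :cols]
    return trimmed.reshape(rows // factor, factor, cols // factor, factor).mean(axis=(1, 3))


def simulate_measurement(
    scene: SceneDefinition,
    library: ComponentLibrary,
    modality: ModalityConfig,
    grid: WavenumberGrid,
    seed: int | None = None,
) -> HyperspectralCube:
    """Simulate one hyperspectral acquisition of ``scene``.

    Per wavenumber the ideal absorbance map (Σ concentration × pure spectrum)
    is blurred with the modality PSF and averaged over detector pixels; each
    pixel then receives a smooth convex baseline drift (random quadratic,
    bounded by ``baseline_drift_amplitude``), a per-cube random multiple of
    the water-vapor spectrum, and zero-mean Gaussian noise of SD
    ``noise_sd_single_scan/√n_coadded_scans``.  Deterministic given the seed.
    """
    if seed is None:
        seed = modality.rng_seed
    ratio_f = modality.pixel_size / scene.fine_step
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-6 or ratio < 1:
        raise ConfigurationError(
            f"pixel_size ({modality.pixel_size}) must be an integer multiple of "
            f"fine_step ({scene.fine_step})"
        )
    if scene.fine_step >= modality.pixel_size and ratio != 1:
        raise ConfigurationError("scene fine grid must be at least as fine as the pixel grid")

    comp_names = [n for n in COMPONENT_NAMES if n != "water_vapor"]
    S = np.stack([resample_to_grid(library[n], grid).absorbance for n in comp_names], axis=1)
    fine_maps = [scene.concentration_maps[n] for n in comp_names]
    n_wn = len(grid)

    if modality.fov_um is not None:
        x0, y0, x1, y1 = modality.fov_um
        j0, j1 = int(round(x0 / scene.fine_step)), int(round(x1 / scene.fine_step))
        i0, i1 = int(round(y0 / scene.fine_step)), int(round(y1 / scene.fine_step))
        if not (0 <= j0 < j1 <= fine_maps[0].shape[1] and 0 <= i0 < i1 <= fine_maps[0].shape[0]):
            raise ConfigurationError(f"fov {modality.fov_um} outside the scene extent")
        window = (slice(i0, i1), slice(j0, j1))
    else:
        window = (slice(None), slice(None))

    if modality.name == "optir":
        # constant PSF: blur each concentration map once on the fine grid
        # (before windowing, so signal from just outside the FOV blurs in)
        sigma_fine = psf_width(modality, grid.values[0]) * _FWHM_TO_SIGMA / scene.fine_step
        binned = [
            _bin_map(
                (gaussian_filter(m, sigma_fine, mode="reflect") if sigma_fine > 0 else m)[window],
                ratio,
            )
            for m in fine_maps
        ]
        conc = np.stack(binned, axis=-1)
        data = conc @ S.T
    else:
        # wavenumber-dependent PSF; σ ≫ pixel, so blur on the detector grid
        binned = [_bin_map(m[window], ratio) for m in fine_maps]
        rows, cols = binned[0].shape
        data = np.zeros((rows, cols, n_wn))
        for j, wn in enumerate(grid.values):
            sigma_px = psf_width(modality, wn) * _FWHM_TO_SIGMA / modality.pixel_size
            for ci in range(len(binned)):
                if S[j, ci] == 0.0:
                    continue
                blurred = (
                    gaussian_filter(binned[ci], sigma_px, mode="reflect")
                    if sigma_px > 0
                    else binned[ci]
                )
                data[:, :, j] += S[j, ci] * blurred

    rows, cols = data.shape[:2]
    rng = np.random.default_rng(seed)

    if modality.baseline_drift_amplitude > 0:
        amp = modality.baseline_drift_amplitude
        x = np.linspace(-1.0, 1.0, n_wn)
        a0 = rng.uniform(0.0, amp / 2.0, size=(rows, cols, 1))
        a1 = rng.uniform(-amp / 8.0, amp / 8.0, size=(rows, cols, 1))
        a2 = rng.uniform(0.0, amp / 4.0, size=(rows, cols, 1))  # convex
        drift = a0 + a1 * x + a2 * x * x
        peak = np.abs(drift).max(axis=2, keepdims=True)
        over = peak > amp
        drift = np.where(over, drift * (amp / np.maximum(peak, 1e-300)), drift)
        data = data + drift

    if modality.atmosphere_strength > 0:
        wv = simulate_atmospheric_reference(modality, grid, library).absorbance
        scale = modality.atmosphere_strength * rng.uniform(0.5, 1.5)
        data = data + scale * wv

    if modality.noise_sd_single_scan > 0:
        sd = modality.noise_sd_single_scan / np.sqrt(modality.n_coadded_scans)
        data = data + rng.normal(0.0, sd, size=data.shape)

    cube = HyperspectralCube(
        pixel_size=modality.pixel_size,
        grid=grid,
        data=data,
        modality=modality.name,
        provenance={
            "seed": str(seed),
            "modality": modality.name,
            "numerical_aperture": str(modality.numerical_aperture),
            "pixel_size_um": str(modality.pixel_size),
            "n_coadded_scans": str(modality.n_coadded_scans),
            "noise_sd_single_scan": str(modality.noise_sd_single_scan),
            "baseline_drift_amplitude": str(modality.baseline_drift_amplitude),
            "atmosphere_strength": str(modality.atmosphere_strength),
            "fov_origin_um": "0,0" if modality.fov_um is None
            else f"{modality.fov_um[0]},{modality.fov_um[1]}",
            **{f"scene_{k}": v for k, v in scene.provenance.items()},
        },
    )
    cube.add_history(f"simulated {modality.name} measurement (seed={seed})")
    return cube
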