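"""Data model and I/O for spectra and hyperspectral cubes.

Conventions used throughout the package:

* the wavenumber axis is stored ascending (plots may reverse it);
* pixels are square; the pixel at (row r, col c) has its center at
  ``((c + 0.5) * pixel_size, (r + 0.5) * pixel_size)`` in µm, origin at the
  top-left corner of the image;
* cube storage is HDF5 (float64), single spectra are 2-column CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, RangeError, ValidationError

FORMAT_VERSION = 1
_MIN_GRID_LEN = 8


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm⁻¹."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < _MIN_GRID_LEN:
            raise ValidationError(
                f"wavenumber grid needs >= {_MIN_GRID_LEN} points, got {values.size}"
            )
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValidationError("wavenumbers must be finite and > 0")
        if np.any(np.diff(values) <= 0):
            raise ValidationError("wavenumbers must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points in the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)

    def index_nearest(self, wavenumber: float) -> int:
        return int(np.argmin(np.abs(self.values - wavenumber)))


def make_grid(lo: float = 860.0, hi: float = 1860.0, step: float = 2.0) -> WavenumberGrid:
    """Uniform grid covering [lo, hi]; default spans the fingerprint window
    with margin outside the 900–1800 cm⁻¹ analysis cut."""
    n = int(round((hi - lo) / step)) + 1
    return WavenumberGrid(np.linspace(lo, hi, n))


@dataclass
class Spectrum:
    """A single absorbance spectrum on a :class:`WavenumberGrid`."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != (len(self.grid),):
            raise ValidationError(
                f"absorbance length {a.shape} does not match grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValidationError("absorbance must be finite everywhere")
        self.absorbance = a

    def copy(self, absorbance: np.ndarray | None = None, label: str | None = None) -> "Spectrum":
        return Spectrum(
            self.grid,
            self.absorbance.copy() if absorbance is None else absorbance,
            self.label if label is None else label,
        )


@dataclass
class HyperspectralCube:
    """Pixel grid × wavenumber axis of absorbance values.

    ``data`` has shape (rows, cols, n_wavenumbers).  ``mask`` (optional) marks
    pixels excluded from downstream statistics (True = masked), e.g. pixels
    whose anchor-peak normalization failed.  ``provenance`` is an append-only
    free-text map; processing steps add numbered ``history_NNNN`` entries.
    """

    pixel_size: float
    grid: WavenumberGrid
    data: np.ndarray
    modality: str = "ground_truth"
    provenance: dict[str, str] = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3 or data.shape[2] != len(self.grid):
            raise ValidationError(
                f"cube data must be rows×cols×{len(self.grid)}, got {data.shape}"
            )
        if data.shape[0] * data.shape[1] < 1:
            raise ValidationError("cube must contain at least one pixel")
        if not (self.pixel_size > 0):
            raise ValidationError("pixel_size must be > 0")
        if not np.all(np.isfinite(data)):
            raise ValidationError("cube absorbance must be finite")
        self.data = data
        if self.mask is not None:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != data.shape[:2]:
                raise ValidationError("mask shape must match the pixel grid")
            self.mask = mask

    @property
    def rows(self) -> int:
        return int(self.data.shape[0])

    @property
    def cols(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_pixels(self) -> int:
        return self.rows * self.cols

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinates in µm as rows×cols arrays."""
        c = (np.arange(self.cols) + 0.5) * self.pixel_size
        r = (np.arange(self.rows) + 0.5) * self.pixel_size
        x, y = np.meshgrid(c, r)
        return x, y

    def spectrum_at(self, row: int, col: int, label: str = "") -> Spectrum:
        return Spectrum(self.grid, self.data[row, col].copy(), label)

    def add_history(self, entry: str) -> None:
        n = sum(1 for k in self.provenance if k.startswith("history_"))
        self.provenance[f"history_{n:04d}"] = entry

    def history(self) -> list[str]:
        keys = sorted(k for k in self.provenance if k.startswith("history_"))
        return [self.provenance[k] for k in keys]


# --------------------------------------------------------------------------
# HDF5 cube I/O


def write_cube(cube: HyperspectralCube, path: str | Path) -> None:
    """Write a cube to the documented HDF5 layout.

    Root attributes ``format_version``, ``pixel_size_um``, ``modality``;
    datasets ``/wavenumbers_cm1`` and ``/absorbance``; provenance as string
    attributes of the ``/provenance`` group.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"directory does not exist: {path.parent}")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["pixel_size_um"] = float(cube.pixel_size)
        f.attrs["modality"] = cube.modality
        f.create_dataset("wavenumbers_cm1", data=cube.grid.values.astype(np.float64))
        f.create_dataset("absorbance", data=cube.data.astype(np.float64))
        prov = f.create_group("provenance")
        for key, value in cube.provenance.items():
            prov.attrs[key] = str(value)
        if cube.mask is not None:
            f.create_dataset("pixel_mask", data=cube.mask.astype(np.uint8))


def read_cube(path: str | Path) -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`.

    The wavenumber order is normalized to ascending regardless of on-disk
    order; duplicated wavenumbers are rejected.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for attr in ("format_version", "pixel_size_um", "modality"):
            if attr not in f.attrs:
                raise FormatError(f"missing root attribute '{attr}' in {path}")
        for dset in ("wavenumbers_cm1", "absorbance"):
            if dset not in f:
                raise FormatError(f"missing dataset '/{dset}' in {path}")
        wn = np.asarray(f["wavenumbers_cm1"], dtype=float)
        data = np.asarray(f["absorbance"], dtype=float)
        if data.ndim != 3:
            raise FormatError("'/absorbance' must be a 3-D dataset")
        order = np.argsort(wn, kind="stable")
        wn = wn[order]
        if np.any(np.diff(wn) <= 0):
            raise ValidationError("duplicate wavenumbers on disk")
        data = data[:, :, order]
        provenance: dict[str, str] = {}
        if "provenance" in f:
            for key, value in f["provenance"].attrs.items():
                provenance[key] = str(value)
        mask = None
        if "pixel_mask" in f:
            mask = np.asarray(f["pixel_mask"], dtype=bool)
        modality = f.attrs["modality"]
        if isinstance(modality, bytes):
            modality = modality.decode()
        return HyperspectralCube(
            pixel_size=float(f.attrs["pixel_size_um"]),
            grid=WavenumberGrid(wn),
            data=data,
            modality=str(modality),
            provenance=provenance,
            mask=mask,
        )


# --------------------------------------------------------------------------
# Spectrum CSV I/O

_CSV_HEADER = ("wavenumber_cm1", "absorbance")


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"directory does not exist: {path.parent}")
    with open(path, "w", newline="\n", encoding="utf-8") as f:
        f.write(",".join(_CSV_HEADER) + "\n")
        for wn, a in zip(spectrum.grid.values, spectrum.absorbance):
            f.write(f"{wn:.12g},{a:.12g}\n")


def read_spectrum_csv(path: str | Path, label: str = "") -> Spectrum:
    """Read a 2-column (wavenumber, absorbance) CSV; header row optional."""
    path = Path(path)
    wns: list[float] = []
    abss: list[float] = []
    with open(path, newline="", encoding="utf-8") as f:
        for lineno, row in enumerate(csv.reader(f), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            try:
                wns.append(float(row[0]))
                abss.append(float(row[1]))
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(f"{path}: line {lineno}: non-numeric cell") from None
    wn = np.asarray(wns)
    ab = np.asarray(abss)
    order = np.argsort(wn, kind="stable")
    return Spectrum(WavenumberGrid(wn[order]), ab[order], label or path.stem)


def resample_to_grid(spectrum: Spectrum, grid: WavenumberGrid) -> Spectrum:
    """Linear interpolation onto ``grid``; exact at shared wavenumbers.

    Raises :class:`RangeError` when the target extends beyond the source span
    (no extrapolation).
    """
    if grid.lo < spectrum.grid.lo - 1e-9 or grid.hi > spectrum.grid.hi + 1e-9:
        raise RangeError(
            f"target grid [{grid.lo}, {grid.hi}] outside source span "
            f"[{spectrum.grid.lo}, {spectrum.grid.hi}]"
        )
    resampled = np.interp(grid.values, spectrum.grid.values, spectrum.absorbance)
    return Spectrum(grid, resampled, spectrum.label)
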