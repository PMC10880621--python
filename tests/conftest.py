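import numpy as np
import pytest

from hyphaspec.spectral_core import HyperspectralCube, Spectrum, WavenumberGrid, make_grid
from hyphaspec.synthetic_scene import default_component_library


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def coarse_grid():
    return make_grid(900.0, 1800.0, 10.0)


@pytest.fixture(scope="session")
def library(grid):
    return default_component_library(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def tiny_cube(rows=2, cols=2, n_wn=16, pixel_size=1.0, seed=0):
    g = WavenumberGrid(np.linspace(1000.0, 1600.0, n_wn))
    r = np.random.default_rng(seed)
    data = r.uniform(0.0, 1.0, size=(rows, cols, n_wn))
    return HyperspectralCube(
        pixel_size=pixel_size,
        grid=g,
        data=data,
        modality="ground_truth",
        provenance={"origin": "test fixture"},
    )


@pytest.fixture
def cube22():
    return tiny_cube()


def gaussian_spectrum(grid, center=1370.0, fwhm=30.0, height=1.0, label=""):
    v = grid.values
    a = height * np.exp(-4.0 * np.log(2.0) * ((v - center) / fwhm) ** 2)
    return Spectrum(grid, a, label)
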