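import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyphaspec.errors import NormalizationError, RangeError
from hyphaspec.preprocess import (
    PreprocessConfig,
    correct_atmosphere,
    crop,
    detect_peaks,
    lower_hull_baseline,
    normalize_to_peak,
    preprocess_cube,
    rubberband_baseline,
)
from hyphaspec.spectral_core import HyperspectralCube, Spectrum, WavenumberGrid
from hyphaspec.synthetic_scene import simulate_deacetylation

from conftest import gaussian_spectrum


def brute_force_lower_hull(x, y):
    """O(n²) oracle: the lower hull is the upper envelope of all chords that
    lie on or below every data point."""
    n = x.size
    baseline = np.full(n, -np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            slope = (y[j] - y[i]) / (x[j] - x[i])
            line = y[i] + slope * (x - x[i])
            if np.all(y >= line - 1e-9):
                span = (x >= x[i]) & (x <= x[j])
                baseline[span] = np.maximum(baseline[span], line[span])
    baseline[0], baseline[-1] = y[0], y[-1]
    return baseline


class TestRubberband:
    def test_affine_spectrum_corrects_to_zero(self, coarse_grid):
        s = Spectrum(coarse_grid, 0.3 + 1e-4 * coarse_grid.values)
        baseline, corrected = rubberband_baseline(s)
        np.testing.assert_allclose(corrected.absorbance, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline.absorbance, s.absorbance, atol=1e-12)

    def test_single_peak_on_zero_baseline(self, coarse_grid):
        s = gaussian_spectrum(coarse_grid, center=1350.0, fwhm=60.0)
        _, corrected = rubberband_baseline(s)
        # endpoints forced to zero, peak essentially preserved
        assert corrected.absorbance[0] == 0.0
        assert corrected.absorbance[-1] == 0.0
        i = coarse_grid.index_nearest(1350.0)
        assert corrected.absorbance[i] == pytest.approx(1.0, abs=0.01)

    def test_peak_plus_convex_drift_matches_oracle(self, coarse_grid):
        v = coarse_grid.values
        drift = 1e-7 * (v - 900.0) ** 2
        s = gaussian_spectrum(coarse_grid, center=1300.0, fwhm=80.0)
        s = s.copy(absorbance=s.absorbance + drift)
        baseline, corrected = rubberband_baseline(s)
        oracle = brute_force_lower_hull(v, s.absorbance)
        np.testing.assert_allclose(baseline.absorbance, oracle, atol=1e-9)
        peak = gaussian_spectrum(coarse_grid, center=1300.0, fwhm=80.0).absorbance
        interior = slice(5, -5)
        assert np.abs(corrected.absorbance - peak)[interior].max() < 0.02

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=8, max_value=64))
    def test_matches_brute_force_oracle_on_random_spectra(self, seed, n):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(900.0, 1800.0, n))
        x += np.arange(n) * 1e-6  # enforce strict monotonicity
        y = rng.uniform(0.0, 2.0, n)
        hull = lower_hull_baseline(x, y)
        oracle = brute_force_lower_hull(x, y)
        np.testing.assert_allclose(hull, oracle, atol=1e-9)
        assert np.all(y - hull >= -1e-9)

    def test_idempotent(self, coarse_grid):
        rng = np.random.default_rng(5)
        s = Spectrum(coarse_grid, rng.uniform(0, 1, len(coarse_grid)))
        _, once = rubberband_baseline(s)
        _, twice = rubberband_baseline(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-9)


class TestCrop:
    def test_closed_interval_contract(self):
        g = WavenumberGrid(np.arange(850.0, 1851.0, 2.0))
        s = Spectrum(g, np.ones(len(g)))
        out = crop(s, 900.0, 1800.0)
        assert out.grid.lo == 900.0
        assert out.grid.hi == 1800.0

    def test_full_span_is_identity(self, coarse_grid):
        s = Spectrum(coarse_grid, np.ones(len(coarse_grid)))
        out = crop(s, coarse_grid.lo, coarse_grid.hi)
        np.testing.assert_array_equal(out.grid.values, coarse_grid.values)

    def test_empty_window_raises(self, coarse_grid):
        s = Spectrum(coarse_grid, np.ones(len(coarse_grid)))
        with pytest.raises(RangeError):
            crop(s, 1900.0, 2000.0)


class TestNormalize:
    def test_divides_by_anchor_window_max(self, coarse_grid):
        s = gaussian_spectrum(coarse_grid, center=1370.0, height=2.0)
        out = normalize_to_peak(s)
        assert out.absorbance.max() == pytest.approx(1.0)
        np.testing.assert_allclose(out.absorbance, s.absorbance / 2.0)

    def test_idempotent(self, coarse_grid):
        s = gaussian_spectrum(coarse_grid, center=1370.0, height=1.0)
        out = normalize_to_peak(normalize_to_peak(s))
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-12)

    def test_all_zero_raises(self, coarse_grid):
        with pytest.raises(NormalizationError):
            normalize_to_peak(Spectrum(coarse_grid, np.zeros(len(coarse_grid))))


class TestAtmosphereCorrection:
    def test_recovers_known_coefficient(self, grid, library):
        wv = library["water_vapor"]
        smooth = gaussian_spectrum(grid, center=1650.0, fwhm=60.0, height=0.5)
        mixed = smooth.copy(absorbance=smooth.absorbance + 0.37 * wv.absorbance)
        corrected = correct_atmosphere(mixed, [wv])
        resid = corrected.absorbance - smooth.absorbance
        assert np.abs(resid).max() < 0.02 * smooth.absorbance.max()
        # grid-search oracle over the coefficient
        mask = grid.window_mask(1300.0, 1800.0)
        best_c, best_r = None, np.inf
        for c in np.arange(0.0, 1.0, 0.005):
            r = np.diff(mixed.absorbance - c * wv.absorbance, 2)[mask[1:-1]]
            rough = float(np.sum(r * r))
            if rough < best_r:
                best_c, best_r = c, rough
        recovered = (mixed.absorbance - corrected.absorbance) / np.maximum(wv.absorbance, 1e-12)
        c_hat = recovered[wv.absorbance > 0.5]
        assert np.allclose(c_hat, 0.37, rtol=0.02)
        assert best_c == pytest.approx(0.37, abs=0.01)

    def test_clean_spectrum_nearly_unchanged(self, grid, library):
        smooth = gaussian_spectrum(grid, center=1600.0, fwhm=80.0)
        corrected = correct_atmosphere(smooth, [library["water_vapor"]])
        assert np.abs(corrected.absorbance - smooth.absorbance).max() < 0.01

    def test_no_references_is_identity(self, grid):
        s = gaussian_spectrum(grid)
        out = correct_atmosphere(s, [])
        np.testing.assert_array_equal(out.absorbance, s.absorbance)

    def test_monte_carlo_recovery_over_coefficient_range(self, grid, library):
        rng = np.random.default_rng(99)
        wv = library["water_vapor"].absorbance
        errs = []
        for _ in range(100):
            c = rng.uniform(0.05, 2.0)
            smooth = gaussian_spectrum(
                grid, center=rng.uniform(1400, 1700), fwhm=rng.uniform(50, 120)
            )
            mixed = smooth.copy(absorbance=smooth.absorbance + c * wv)
            corrected = correct_atmosphere(mixed, [library["water_vapor"]])
            strong = wv > 0.5
            c_hat = np.mean((mixed.absorbance - corrected.absorbance)[strong] / wv[strong])
            errs.append(abs(c_hat - c) / c)
        assert max(errs) <= 0.05


class TestCubePipeline:
    def _film_cube(self, grid, library, rows=3, cols=4):
        base = library["cellulose"].absorbance
        data = np.tile(base, (rows, cols, 1)) * np.linspace(
            0.5, 1.5, rows * cols
        ).reshape(rows, cols, 1)
        return HyperspectralCube(pixel_size=1.0, grid=grid, data=data, modality="optir")

    def test_empty_steps_is_identity(self, grid, library):
        cube = self._film_cube(grid, library)
        out = preprocess_cube(cube, PreprocessConfig(steps=()))
        np.testing.assert_array_equal(out.data, cube.data)

    def test_normalization_contract_on_every_pixel(self, grid, library):
        cube = self._film_cube(grid, library)
        out = preprocess_cube(cube, PreprocessConfig())
        cfg = PreprocessConfig()
        window = out.grid.window_mask(cfg.anchor - cfg.anchor_window, cfg.anchor + cfg.anchor_window)
        peaks = out.data[:, :, window].max(axis=2)
        np.testing.assert_allclose(peaks, 1.0, atol=1e-12)
        assert not out.mask.any()

    def test_rubberband_pass_is_idempotent_on_cube(self, grid, library):
        cube = self._film_cube(grid, library)
        cfg = PreprocessConfig(steps=("rubberband",))
        once = preprocess_cube(cube, cfg)
        twice = preprocess_cube(once, cfg)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-9)

    def test_scale_invariance_of_normalized_output(self, grid, library):
        cube = self._film_cube(grid, library)
        scaled = HyperspectralCube(
            pixel_size=1.0, grid=grid, data=cube.data * 7.3, modality="optir"
        )
        cfg = PreprocessConfig(steps=("rubberband", "normalize"))
        a = preprocess_cube(cube, cfg)
        b = preprocess_cube(scaled, cfg)
        np.testing.assert_allclose(a.data, b.data, atol=1e-9)

    def test_zero_pixels_are_masked_not_zero_filled(self, grid, library):
        cube = self._film_cube(grid, library)
        cube.data[0, 0] = 0.0
        out = preprocess_cube(cube, PreprocessConfig(steps=("crop", "normalize")))
        assert out.mask[0, 0]
        assert int(out.provenance["masked_pixels"]) == 1

    def test_yaml_round_trip_rejects_unknown_keys(self):
        cfg = PreprocessConfig(crop_lo=950.0)
        back = PreprocessConfig.from_yaml(cfg.to_yaml())
        assert back == cfg
        from hyphaspec.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            PreprocessConfig.from_yaml("crop_lo: 900\nbogus_key: 1\n")


class TestDetectPeaks:
    def test_protein_top_two(self, library):
        peaks = detect_peaks(library["protein"])
        assert peaks[0][0] == pytest.approx(1650.0, abs=2.0)
        assert peaks[1][0] == pytest.approx(1550.0, abs=2.0)

    def test_complete_deacetylation_removes_acetate_band(self, library):
        s = simulate_deacetylation(library, 0.0)
        peaks = detect_peaks(s, min_height=0.02)
        assert not any(abs(c - 1742.0) <= 10.0 for c, _ in peaks)

    def test_flat_spectrum_has_no_peaks(self, coarse_grid):
        s = Spectrum(coarse_grid, np.zeros(len(coarse_grid)))
        assert detect_peaks(s) == []
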