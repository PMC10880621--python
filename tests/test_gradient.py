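import numpy as np
import pytest

from hyphaspec.errors import InsufficientSupportError, ValidationError
from hyphaspec.gradient import (
    GradientProfile,
    lowess_trend,
    make_radial_cuts,
    select_pixels_near_cuts,
    two_component_profile,
    zone_linearity,
)
from hyphaspec.segmentation import ZoneGeometry, measure_zone_geometry
from hyphaspec.spectral_core import HyperspectralCube, Spectrum, WavenumberGrid
from hyphaspec.unmixing import UnmixingResult

from test_segmentation import painted_cluster_map


@pytest.fixture()
def painted():
    return painted_cluster_map(rows=60, cols=48, pixel_size=0.5)


class TestMakeRadialCuts:
    def test_single_cut_points_outward_along_axis(self, painted):
        cuts = make_radial_cuts(painted, n_cuts=1, fan_degrees=0.0, max_length=8.0)
        assert len(cuts.directions) == 1
        d = np.array([np.cos(cuts.directions[0]), np.sin(cuts.directions[0])])
        # stripe axis is horizontal; outward = +x by the axis sign convention
        assert abs(d[1]) < 1e-6
        assert d[0] > 0

    def test_fan_angular_spacing(self, painted):
        cuts = make_radial_cuts(painted, n_cuts=5, fan_degrees=90.0, max_length=8.0)
        spacing = np.diff(cuts.directions)
        np.testing.assert_allclose(np.rad2deg(spacing), 22.5, atol=1e-9)

    def test_rays_clipped_at_image_boundary_and_flagged(self, painted):
        cuts = make_radial_cuts(painted, n_cuts=1, fan_degrees=0.0, max_length=500.0)
        assert cuts.clipped[0]
        x1, y1 = cuts.endpoints[0]
        assert 0.0 <= x1 <= 48 * 0.5 + 1e-9
        assert 0.0 <= y1 <= 60 * 0.5 + 1e-9


class TestSelectPixels:
    def _cube_for(self, cmap, fill=1.0):
        g = WavenumberGrid(np.linspace(1000.0, 1700.0, 16))
        data = np.full(cmap.shape + (16,), fill)
        return HyperspectralCube(pixel_size=cmap.pixel_size, grid=g, data=data,
                                 modality="optir")

    def test_halfwidth_monotonicity(self, painted):
        cube = self._cube_for(painted)
        narrow = make_radial_cuts(painted, n_cuts=3, fan_degrees=60.0, max_length=8.0,
                                  selection_halfwidth=0.25)
        wide = make_radial_cuts(painted, n_cuts=3, fan_degrees=60.0, max_length=8.0,
                                selection_halfwidth=0.75)
        sel_narrow = select_pixels_near_cuts(narrow, cube, painted)
        sel_wide = select_pixels_near_cuts(wide, cube, painted)
        pix_narrow = {(r, c) for r, c, _ in sel_narrow.selected_pixels}
        pix_wide = {(r, c) for r, c, _ in sel_wide.selected_pixels}
        assert pix_narrow <= pix_wide

    def test_selection_excludes_hypha_and_guard_ring(self, painted):
        cube = self._cube_for(painted)
        cuts = make_radial_cuts(painted, n_cuts=5, fan_degrees=120.0, max_length=10.0)
        sel = select_pixels_near_cuts(cuts, cube, painted)
        labels = painted.labels
        for r, c, _d in sel.selected_pixels:
            assert labels[r, c] != 2
            rr = slice(max(r - 1, 0), r + 2)
            cc = slice(max(c - 1, 0), c + 2)
            assert not np.any(labels[rr, cc] == 2)

    def test_duplicates_counted_once(self, painted):
        cube = self._cube_for(painted)
        cuts = make_radial_cuts(painted, n_cuts=6, fan_degrees=30.0, max_length=8.0)
        sel = select_pixels_near_cuts(cuts, cube, painted)
        pix = [(r, c) for r, c, _ in sel.selected_pixels]
        assert len(pix) == len(set(pix))


def linear_gradient_cube(painted, n_wn=41, noise=0.0, seed=0):
    """Spectra mixing two synthetic components linearly in the distance
    coordinate the profile reports (capsule distance to the measured
    midline): the 'oxidized' fraction rises from 0 at the hyphal edge to 0.6
    at the zone boundary and is zero outside it."""
    from hyphaspec.geometry import segment_distance

    rng = np.random.default_rng(seed)
    g = WavenumberGrid(np.linspace(1000.0, 1700.0, n_wn))
    v = np.linspace(0.0, 1.0, n_wn)
    cell = np.exp(-((v - 0.2) / 0.15) ** 2)
    oxid = 0.6 * np.exp(-((v - 0.2) / 0.15) ** 2) + np.exp(-((v - 0.9) / 0.08) ** 2)
    rows, cols = painted.shape
    ps = painted.pixel_size
    geom = measure_zone_geometry(painted)
    p0, p1 = geom.midline_estimate
    x = (np.arange(cols) + 0.5) * ps
    y = (np.arange(rows) + 0.5) * ps
    xx, yy = np.meshgrid(x, y)
    d = segment_distance(xx, yy, p0, p1)
    e = d - geom.hypha_width / 2.0
    frac = 0.6 * np.clip(e, 0.0, None) / geom.halo_extent
    frac[e >= geom.halo_extent] = 0.0
    data = (1.0 - frac)[:, :, None] * cell + frac[:, :, None] * oxid
    data += rng.normal(0, noise, size=data.shape)
    return HyperspectralCube(pixel_size=ps, grid=g, data=np.clip(data, 0, None),
                             modality="optir")


class TestTwoComponentProfile:
    def test_exact_linear_gradient_recovered(self, painted):
        cube = linear_gradient_cube(painted)
        cuts = make_radial_cuts(painted, n_cuts=6, fan_degrees=150.0, max_length=10.0)
        cuts = select_pixels_near_cuts(cuts, cube, painted)
        profile = two_component_profile(cube, cuts)
        geom = measure_zone_geometry(painted)
        fit = zone_linearity(profile, geom, boundary_buffer=cube.pixel_size)
        assert fit.r2_in >= 0.999
        assert abs(fit.slope_out) <= 0.01 * abs(fit.slope_in)

    def test_identical_spectra_are_degenerate_for_two_components(self, painted):
        # a rank-one data matrix cannot support a 2-component model; the
        # unmixing degeneracy propagates out of the profile
        from hyphaspec.errors import DegeneracyError

        cube = linear_gradient_cube(painted)
        flat = cube.data[0, 0].copy()
        cube.data[:, :, :] = flat
        cuts = make_radial_cuts(painted, n_cuts=6, fan_degrees=150.0, max_length=10.0)
        cuts = select_pixels_near_cuts(cuts, cube, painted)
        with pytest.raises(DegeneracyError):
            two_component_profile(cube, cuts)

    def test_decomposition_component_has_larger_co_amplitude(self, painted):
        cube = linear_gradient_cube(painted)
        cuts = make_radial_cuts(painted, n_cuts=6, fan_degrees=150.0, max_length=10.0)
        cuts = select_pixels_near_cuts(cuts, cube, painted)
        profile = two_component_profile(cube, cuts)
        window = cube.grid.window_mask(1600.0, 1700.0)
        amp = profile.unmixing.S[window].mean(axis=0)
        assert amp[profile.decomposition_index] == amp.max()

    def test_rescaling_all_spectra_leaves_profile_shape(self, painted):
        cube = linear_gradient_cube(painted)
        cuts = make_radial_cuts(painted, n_cuts=6, fan_degrees=150.0, max_length=10.0)
        cuts = select_pixels_near_cuts(cuts, cube, painted)
        p1 = two_component_profile(cube, cuts)
        scaled = HyperspectralCube(pixel_size=cube.pixel_size, grid=cube.grid,
                                   data=cube.data * 3.7, modality="optir")
        p2 = two_component_profile(scaled, cuts)
        c1 = p1.decomposition_contribution
        c2 = p2.decomposition_contribution
        assert np.corrcoef(c1, c2)[0, 1] > 0.9999


class TestLowess:
    def _profile(self, x, y):
        g = WavenumberGrid(np.linspace(1000.0, 1700.0, 16))
        comps = [Spectrum(g, np.ones(16)), Spectrum(g, np.ones(16))]
        C = np.stack([y, 1.0 - y * 0.1], axis=1)
        dummy = UnmixingResult(
            S=np.ones((16, 2)), C=C, k=2, lof_percent=0.0, n_iterations=1,
            converged=True, pure_variables=np.array([0, 1]),
        )
        return GradientProfile(
            distances=x, contributions=C, components=comps,
            decomposition_index=0, pixel_index=np.zeros((x.size, 2), dtype=int),
            unmixing=dummy,
        )

    def test_exact_line_reproduced(self):
        x = np.linspace(0.0, 10.0, 60)
        y = 0.3 + 0.05 * x
        profile = lowess_trend(self._profile(x, y), frac=0.3)
        tx, ty = profile.lowess_trend[0]
        np.testing.assert_allclose(ty, 0.3 + 0.05 * tx, atol=1e-6)

    def test_constant_with_noise_within_three_se(self, rng):
        x = np.sort(rng.uniform(0, 10, 200))
        y = 0.5 + rng.normal(0, 0.05, 200)
        profile = lowess_trend(self._profile(x, y), frac=0.5)
        _, ty = profile.lowess_trend[0]
        se = 0.05 / np.sqrt(200 * 0.5)
        assert np.abs(ty - 0.5).max() < 3.0 * se * 3.0

    def test_frac_out_of_range(self):
        x = np.linspace(0, 10, 30)
        with pytest.raises(ValidationError):
            lowess_trend(self._profile(x, x), frac=1.5)


class TestZoneLinearity:
    def _geom(self):
        return ZoneGeometry(hypha_width=4.5, halo_extent=6.0,
                            midline_estimate=((0.0, 0.0), (1.0, 0.0)),
                            station_widths=[], station_halos={})

    def _profile_from(self, d, c):
        g = WavenumberGrid(np.linspace(1000.0, 1700.0, 16))
        comps = [Spectrum(g, np.ones(16)), Spectrum(g, np.ones(16))]
        C = np.stack([c, 1.0 - 0.1 * c], axis=1)
        dummy = UnmixingResult(S=np.ones((16, 2)), C=C, k=2, lof_percent=0.0,
                               n_iterations=1, converged=True,
                               pure_variables=np.array([0, 1]))
        return GradientProfile(distances=d, contributions=C, components=comps,
                               decomposition_index=0,
                               pixel_index=np.zeros((d.size, 2), dtype=int),
                               unmixing=dummy)

    def test_exact_ramp_and_flat_outside(self):
        d = np.linspace(2.25, 14.0, 120)
        c = np.where(d <= 8.25, 0.1 * (d - 2.25), 0.6)
        c = np.where(d > 8.25, 0.0, c)  # zero beyond the zone
        fit = zone_linearity(self._profile_from(d, c), self._geom())
        assert fit.r2_in == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_out == pytest.approx(0.0, abs=1e-12)

    def test_shuffled_distances_destroy_fit(self, rng):
        d = np.linspace(2.25, 14.0, 120)
        c = np.clip(0.1 * (d - 2.25), 0, 0.6)
        shuffled = d.copy()
        rng.shuffle(shuffled)
        fit = zone_linearity(self._profile_from(shuffled, c), self._geom())
        assert fit.r2_in < 0.2

    def test_too_few_points_raise(self):
        d = np.array([3.0, 4.0, 5.0, 9.0])
        with pytest.raises(InsufficientSupportError):
            zone_linearity(self._profile_from(d, d * 0.1), self._geom())
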