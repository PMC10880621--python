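# hyphaspec

Hyperspectral infrared microspectroscopy analysis of fungal cellulose
decomposition around single hyphae.

When a fungal hypha grows on a thin regenerated-cellulose film it oxidizes
the film in a halo around itself. Hyperspectral IR imaging can map this
chemistry — every pixel carries a full absorbance spectrum — but conventional
IR microspectroscopy is diffraction-limited by the IR wavelength itself
(16.9 µm at 900 cm⁻¹, 8.5 µm at 1800 cm⁻¹ for an NA 0.4 objective), while
optical photothermal IR (O-PTIR) reads the same absorption through a 532 nm
probe laser and resolves 416 nm (NA 0.78). `hyphaspec` implements the
complete analysis chain for such images and a synthetic scene + instrument
simulator that makes every stage verifiable without experimental data. It is
written for spectroscopists and image analysts who want a tested, scriptable
version of this workflow.

## The analysis

Given a cube `D` (pixels × wavenumbers, 900–1800 cm⁻¹), the chain is:

1. **Atmospheric correction** — subtract fitted water-vapor reference lines
   (coefficients minimize the roughness Σ(Δ²a)² of the residual over
   1300–1800 cm⁻¹).
2. **Crop** to 900–1800 cm⁻¹ and **rubberband baseline** — subtract the
   lower convex hull of each spectrum.
3. **Normalize** each pixel to its cellulose CH-bend peak at 1370 cm⁻¹.
4. **SIMPLISMA** pure-variable selection: purity of channel *j* is
   `p_j = σ_j / (μ_j + α·max μ)` with determinant-based independence
   weighting; the selected channels initialize
5. **MCR-ALS**: `D ≈ C·Sᵀ` with `C, S ≥ 0`, alternating exact non-negative
   least squares, spectra scaled to unit maximum, convergence tracked by the
   lack of fit `LOF = 100·√(Σ(D−CSᵀ)²/ΣD²)` (non-increasing by
   construction).
6. **k-means (k = 3)** on the standardized contribution vectors; clusters
   are labeled background / decomposition zone / hypha by their mean
   absorbance in the amide/carbonyl window (1500–1700 cm⁻¹), and zone
   geometry (hypha width, halo extent) is measured in µm from cross-sections
   perpendicular to the hypha's principal axis.
7. **Radial gradient** — pixels near radial cuts from the hyphal tip are
   unmixed with two components; the contribution of the C=O-carrying
   component vs distance to the hyphal midline is smoothed with lowess and
   fitted piecewise (linear inside the zone, flat outside).

The simulator builds pure-component spectra (cellulose, cellulose acetate,
oxidized cellulose, protein, water vapor) from parametric band lists, paints
a ground-truth scene (4.6 µm hypha, 6.3 µm decomposition halo with a linear
oxidation gradient), and measures it through either instrument model:
Gaussian PSF with FWHM = 0.61·λ/NA (wavenumber-dependent for conventional
IR, fixed at the 416 nm probe spot for O-PTIR), pixel integration
(2.3 µm / 1024 scans vs 0.5 µm / 3 scans), convex baseline drift,
atmospheric lines, and shot-to-shot noise scaled by 1/√(co-added scans).

## Worked example

```bash
hyphaspec generate --preset fig3_optir --seed 1 --out run/
hyphaspec analyze run/fig3_optir_seed1.h5 --out run/report
```

The analyze step prints (seed 1):

```json
{
  "lof_percent": 3.29,
  "n_iterations": 66,
  "hypha_width_um": 4.5,
  "halo_extent_um": 6.5,
  "masked_pixels": 0,
  ...
}
```

meaning the three-component MCR-ALS model reproduces the preprocessed cube
to a 3.3 % lack of fit, and the segmented zone map measures a 4.5 µm-wide
hypha cluster with a decomposition halo reaching 6.5 µm from the hyphal
edge — recovering the 4.6 / 6.3 µm the scene was built with to within one
0.5 µm pixel. `run/report/` also contains the cluster map (blue background,
orange decomposition zone, green hypha), per-zone mean ± SD spectra, the
MCR component spectra and contributions, and the radial gradient profile
with its lowess trend and zone fits. The same scene simulated through the
conventional instrument (`--preset fig2_conventional`) yields an apparent
halo of ~9 µm — the diffraction-blurred view that O-PTIR sharpens.

Other commands: `hyphaspec resolution --wavenumber 900 --na 0.4` (prints
16.9 µm), `hyphaspec report --preset fig3_optir` (summary figures).

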