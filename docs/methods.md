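# Methods

This note documents the models behind `hyphaspec`: what the synthetic scene
and the two instrument models emulate, the analysis chain and its numerical
choices, and what the package's tests do and do not demonstrate about real
measurements.

## Scene model

The ground truth is a set of per-component concentration maps on a fine
spatial grid (default 0.1 µm — at least four samples per detector pixel and
well below the 416 nm O-PTIR spot). A single hypha is a capsule: points
within `hypha_width/2` (default 4.6 µm) of a midline segment. Substrate is
either a regenerated-cellulose film or bare gold.

**Oxidation gradient.** Within the decomposition zone the film is a linear
mixture of cellulose and oxidized cellulose. The degree of oxidation rises
linearly from 0 at the hyphal edge to `oxidation_max` (default 0.6) at the
outer zone boundary (`halo_extent`, default 6.3 µm from the edge) and is
zero beyond it. Two consequences drive the design: the radial contribution
profile of the decomposition-signature component is linear in distance
inside the zone and flat outside it, which is the measured trend this
generator emulates; and the outer boundary is a sharp chemical edge, which
is what a three-cluster segmentation can localize. (A ramp that instead
*decays* to zero at the boundary has no detectable edge: a k-means boundary
between a ramp and a large uniform background necessarily sits at ≥ 25 % of
the ramp — midpoint-of-centroids argument — so no clustering could recover
the zone extent under that law.) Outside the hypha the cellulose and
oxidized-cellulose fractions sum to one.

**Hypha interior.** The hypha contains protein at `protein_density`
(default 1.0) and attenuates the film signal beneath it by the opacity
factor β = 0.7 (free emulation parameter): hyphal spectra are
protein-dominated with weak carbohydrate bands, as observed. The film under
the hypha is unoxidized (the gradient starts at the edge).

**Preset geometry.** The `fig2_conventional` / `fig3_optir` presets share
one scene sized to the conventional instrument's field of view (64 × 64
detector elements × 2.3 µm ≈ 147 × 147 µm); the O-PTIR modality images a
48 × 40 µm sub-region centered on the hypha, mirroring how the
high-resolution raster covers a small window of the survey image. The field
size matters: the k-means boundary between the decomposition and background
clusters shifts with the background mass fraction, so the FOV is part of
the acquisition, not a free parameter. The midline is placed incommensurate
with both pixel grids (endpoints at x.07/x.13 µm): aligning it exactly with
a pixel boundary is a measure-zero configuration that deterministically
biases width estimates a full pixel low, and no real scene is so aligned.
`fig5_gold` is a hypha on bare gold (no film, no halo) on a 20 × 16 µm
scene.

## Pure-component spectra

Components are sums of Gaussian/Lorentzian bands
(`h·exp(−4 ln2 ((ν−c)/fwhm)²)`, `h/(1+(2(ν−c)/fwhm)²)`). The named centers
are the literature assignments: cellulose C–O stretch complex (strongest
absorbance in 1100–950 cm⁻¹), C–O–C ether at 1160 cm⁻¹, CH bend at
1370 cm⁻¹ (the normalization anchor); protein amide I/II at 1650/1550 cm⁻¹;
acetate ester bands at 1742/1219 cm⁻¹ on top of cellulose; oxidized
cellulose is cellulose with the 1100–950 cm⁻¹ bands scaled by 0.55 and a
carbonyl/carboxylate band added at 1625 cm⁻¹; water vapor is a comb of
narrow (3 cm⁻¹) lines confined to 1300–1800 cm⁻¹. Widths and heights beyond
the named centers are invented emulation parameters; every band list is
stored on the `ComponentLibrary` so tests assert against provenance, not
duplicated constants. `simulate_deacetylation(residual)` interpolates
linearly between cellulose (0) and cellulose acetate (1) for the film-QC
workflow.

## Instrument models

Both instruments are modelled as: ideal absorbance map per wavenumber
(Σ concentration × pure spectrum) → isotropic Gaussian PSF → detector-pixel
averaging → per-pixel additive artifacts. The PSF FWHM equals the Rayleigh
resolution 0.61·λ/NA: wavenumber-dependent for conventional IR (16.9 µm at
900 cm⁻¹ → 8.5 µm at 1800 cm⁻¹, NA 0.4), constant 416 nm for O-PTIR
(532 nm probe, NA 0.78). Convolution uses reflecting boundaries so scene
edges are not darkened into spurious zones. For O-PTIR the (constant) blur
is applied once per concentration map on the fine grid; for conventional IR,
whose blur is far wider than the 2.3 µm pixel, maps are first pixel-averaged
and the per-wavenumber blur applied on the detector grid (the two orders
commute up to a sub-percent resampling error at σ ≳ 1.5 pixels).

Additive artifacts per pixel: a random convex quadratic baseline
(amplitude ≤ 0.03 absorbance), one per-cube random multiple of the
water-vapor spectrum (strength 0.2 × U[0.5, 1.5]), and i.i.d. Gaussian noise
with SD `noise_sd_single_scan/√n_coadded_scans` (0.02 single-scan for both
instruments → ≈ 0.0115 for O-PTIR's 3 scans, ≈ 0.0006 for the conventional
1024). Noise magnitudes are emulation parameters, not measured values. CO₂
is omitted: its bands (≈ 667 and 2349 cm⁻¹) lie outside 900–1800 cm⁻¹,
though the correction API accepts any reference list. All randomness flows
from a single seed; cubes are bit-reproducible.

## Analysis chain

Steps run in the fixed order atmosphere → crop → rubberband → normalize.

* **Atmospheric correction** subtracts Σ c_k·reference_k with coefficients
  minimizing the sum of squared second differences of the corrected spectrum
  over 1300–1800 cm⁻¹ — sharp rotational-vibrational lines dominate the
  roughness, broad sample bands barely contribute, so the fit removes gas
  lines without eating sample signal (recovery error ≤ 5 % for coefficients
  in [0.05, 2]).
* **Rubberband** subtracts the lower convex hull (monotone-chain
  construction, O(n); verified exactly against an O(n²) chord-enumeration
  oracle). Output is non-negative, zero at the hull vertices, idempotent.
* **Normalization** divides by the maximum within 1370 ± 15 cm⁻¹ (peak
  height, not area; the window tolerates band-position jitter). Pixels whose
  anchor maximum falls below 10⁻⁶ are masked, not zero-filled; on bare gold
  there is no anchor at all, so gold scenes are analyzed unnormalized.
* **SIMPLISMA** (α = 0.05): purity σ/(μ + α·max μ); subsequent picks are
  weighted by the determinant of the correlation-around-origin matrix of the
  candidate joined with the already-selected columns; ties break to the
  lowest index. The selected pure-variable columns, scaled to unit maximum,
  are the initial *contribution* estimates for MCR-ALS (a column of the
  pixels × wavenumbers matrix is a spatial profile).
* **MCR-ALS**: each half-step is the exact row-wise NNLS optimum. For
  k ≤ 6 this is solved by enumerating the 2^k active sets with a shared
  normal matrix, vectorized over all rows — exact (the optimum's support
  yields a stationary, feasible candidate by KKT) and orders of magnitude
  faster than per-row active-set iteration; scipy's solver is the fallback
  for larger k and the oracle in tests. Exactness guarantees a
  non-increasing LOF. Spectra are rescaled to unit maximum each iteration
  (scale folded into C); convergence when |ΔLOF| < 10⁻⁶·LOF, cap 500
  iterations (`converged=False` returned, not raised). Rotational ambiguity
  is inherent: tests assert cosine similarity after optimal matching, never
  elementwise equality. k = 3 for full images (film, oxidized film,
  protein); k = 2 for the radial profile.
* **Segmentation**: k-means (k = 3, n_init = 10, fixed seed) on per-column
  standardized contributions. Semantic labels by mean normalized absorbance
  over 1500–1700 cm⁻¹: highest → hypha, middle → decomposition, lowest →
  background (ties beyond 10⁻⁹ raise). Two-cluster scenes (gold) get
  hypha/background and a provenance flag.
* **Zone geometry**: midline = principal axis of hypha-labeled pixel
  centers, with the axis span shrunk by half the measured width at each end
  (the pixel span includes the rounded tip caps; the midline of a capsule
  excludes them). At stations one pixel apart, perpendicular cross-sections
  are sampled at pixel steps: width = run length of hypha labels (median
  over stations), halo = distance from the run's outer edge to the last
  decomposition-labeled sample (median per side, sides averaged). Medians
  resist the ragged tip. With the rising gradient, the inner part of the
  halo is chemically near-background and clusters with it; the *last*
  decomposition pixel localizes the sharp outer boundary, which is the
  quantity reported.
* **Gradient**: six cuts fanned over 150° from the hypha-boundary pixel
  nearest the tip, length 12 µm, selection halfwidth one pixel (defaults
  chosen to select a few hundred pixels on the O-PTIR preset). The hypha
  plus a one-pixel guard ring is excluded — boundary pixels straddle the
  cell wall and leak amide signal that would otherwise hijack one of the two
  MCR components. Distances are to the hyphal midline. The
  decomposition-signature component is the one with greater mean amplitude
  over 1600–1700 cm⁻¹ (C=O). Lowess: tricube local linear, frac 0.3, two
  robustifying iterations (evaluated at the data, averaged over duplicate
  distances). Zone fits exclude a one-pixel band at the measured outer
  boundary from both sides: the boundary is known only to pixel precision
  and pixels straddling it mix the zones.

## What passing tests show — and don't

The simulator provides exact ground truth, so the tests demonstrate that the
chain is *self-consistent*: it recovers the geometry, gradient law and band
positions it was fed, through realistic blur, drift, gas lines and noise,
and that each numerical primitive matches an independent oracle. They do not
validate the physics the simulator omits: Mie/resonant scattering,
photothermal-lens formation, detector nonlinearity, sample thickness
effects, hyphal 3-D morphology, or multiple/branching hyphae. Real
conventional-IR data in particular mix thickness and scattering effects into
exactly the amide window the segmentation ranks on; the simulator's clean
separation is optimistic there. The apparent hypha cluster in the simulated
conventional modality is itself diffraction-inflated (≈ 9 µm), which
shortens the halo measured from its edge; the reported conventional halo is
therefore a conservative lower bound on the inflation.

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `hypha_width` | 4.6 µm | capsule diameter |
| `halo_extent` | 6.3 µm | hyphal edge → outer zone boundary |
| `oxidation_max` | 0.6 | degree of conversion at the boundary |
| `protein_density` | 1.0 | hypha protein concentration |
| `hypha_opacity` β | 0.7 | film signal blocked under the hypha |
| `fine_step` | 0.1 µm | ground-truth grid |
| `noise_sd_single_scan` | 0.02 | per-channel, absorbance |
| `baseline_drift_amplitude` | 0.03 | convex quadratic bound |
| `atmosphere_strength` | 0.2 | water-vapor admixture scale |
| crop | 900–1800 cm⁻¹ | analysis window |
| anchor | 1370 ± 15 cm⁻¹ | normalization peak |
| SIMPLISMA α | 0.05 | purity noise offset |
| MCR tol / max_iter | 10⁻⁶ / 500 | relative LOF change |
| k-means | k=3, n_init=10 | fixed recorded seed |
| cuts / fan / length | 6 / 150° / 12 µm | radial selection |
| lowess frac / it | 0.3 / 2 | trend smoothing |

Problem sizes used throughout: 96 × 80 pixel O-PTIR cubes and 64 × 64
conventional cubes on a 501-point wavenumber grid (860–1860 cm⁻¹, 2 cm⁻¹
step), five replicate seeds for stochastic quantities.
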