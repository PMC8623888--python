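# Methods

## Scope and model of the study

`granmorph` re-creates, on fully synthetic inputs, the analysis chain used to
characterise high-shear wet granulation (HSWG) of microcrystalline cellulose:
dynamic image analysis (DIA) of individual granules, batch-level granulometry,
and quadratic response-surface modelling of mean granule size and process
yield against the liquid-to-solid ratio (L/S) and impeller speed (IS, rpm).
The raw experimental data behind the original campaign are not publicly
deposited, so the package treats the *published fitted surfaces* as ground
truth and builds generators around them; everything downstream is then
testable against closed forms or against those printed coefficient sets.

The two reference surfaces (natural units; response in mm and %):

```
d_mean = 3.22765 − 6.10009·(L/S) + 0.000907·IS − 0.002795·(L/S·IS)
         + 4.41496·(L/S)² + 1.0458e−6·IS²

yield  = −286.33147 + 425.81688·(L/S) + 0.228893·IS + 0.056508·(L/S·IS)
         − 146.81044·(L/S)² − 0.000257·IS²
```

are shipped verbatim in `rsm.reference_models()`, together with their
published ANOVA tables (`rsm.reference_anova_tables()`).

## Synthetic particles and silhouette rendering

**Particle model.** Real HSWG granules are rounded, slightly rough and mildly
elongated. The generator uses a star-convex radial model: a triaxial
ellipsoid (semi-axes a ≥ b ≥ c, mm) modulated by a smooth angular roughness
term, r(u) = r_ellipsoid(u)·(1 + ρ·f(u)). f is a seeded sum of six Chebyshev
ridges Σ cᵢ·T_k(u·vᵢ) over random unit directions, normalised by Σ|cᵢ| so
|f| ≤ 1 *analytically* — the relative perturbation is bounded by the
roughness amplitude ρ exactly, not just empirically, and ρ < 0.5 guarantees
the shape stays star-convex about its centroid. The wavenumber k sets the
angular frequency of the bumps. This model was chosen because every limiting
descriptor (sphere → all shape factors 1; prolate spheroid → aspect ratio
b/a) has a closed form, which is what the test suite leans on.

**Orientation and projection.** Each frame views the particle under an
independent uniformly random rotation (seeded unit quaternions), emulating
an instrument stream of tumbling particles photographed at a high frame
rate. Projection of a star-convex body along the camera axis is star-convex
about the projected centroid, so the silhouette is fully described by a
periodic radial profile g(ψ). The renderer samples 60 000 Fibonacci-lattice
surface points, projects them, takes the per-azimuth maximum radius over
1 440 bins (0.25°), and rasterises with the rule *a pixel is foreground when
its centre lies inside the silhouette*. A particle that would not fit with a
2-pixel margin raises an error rather than clipping. Rarely, a single stray
pixel survives at a steep profile gradient; the renderer keeps the largest
connected component so each frame is one 8-connected blob. Bin-maximum
sampling biases the profile low by O(bin width²) ≈ 10⁻⁴ relative — far below
the rasterisation error at the default 0.01 mm/px.

**Experiment tables.** `simulate_experiment_table` evaluates both reference
surfaces on a full-factorial design (defaults: L/S ∈ {0.70, 0.85, 1.00,
1.15, 1.27} × IS ∈ {300, 500, 700} rpm — the experimental ranges of the
original campaign) and adds seeded Gaussian noise. The two responses live on
incommensurate scales, so the design carries two noise fields: 0.077 mm for
d_mean (the prediction standard deviation reported for the published size
model) and 9.6 % for yield (the square root of the residual mean square
implied by the published yield ANOVA, MS_model/F_model = 12679.65/138.32).
Yields are clamped to [0, 100] % since they are physical percentages; at the
design corners the reference surface itself strays slightly outside that
interval, so a refit on clamped noisy data is mildly attenuated — visible in
`analysis/04` as yield coefficients a few percent short of the reference,
while the d_mean refit recovers its reference to ~2 %.

**Per-granule sizes.** No per-granule distributions were published, only
batch summaries, so the size generator is an explicitly labelled stand-in: a
lognormal with configurable geometric standard deviation (default 1.5,
a typical right-skewed granule population), parameterised so its
*arithmetic* mean equals the reference-surface prediction at (L/S, IS).
Dispersion 1 degenerates to all-equal diameters. Because the anchor is
arithmetic, batch mean sizes computed from these samples must use
number-weighted class histograms (see below).

## DIA morphometry

**Contours and area.** Each mask's boundary is the longest marching-squares
contour at level 0.5 of the zero-padded mask (pixel centres at integer
coordinates, origin top-left, row-major). Area is the shoelace area of that
sub-pixel polygon.

**Perimeter.** The raw pixel-edge boundary overestimates a disk's perimeter
by ~27 %, which would push sphericity far off; even the marching-squares
polygon carries a half-pixel staircase. The default estimator measures the
contour after a circular moving average over 7 vertices, which removes the
staircase oscillation while shortening a radius-100 px disk's perimeter by
<0.2 %. The window is a parameter (`smooth_window`, 0 disables) and
auto-shrinks for tiny contours.

**Convex hull and Feret extremes.** The hull is built over the contour after
a *light* 3-vertex smoothing: the raw staircase inflates the hull of a
convex outline by ~0.5 %, while 3-vertex smoothing keeps genuine corners
(cross-shape concavity stays within 1.2 % of its 2/7 closed form). The hull
area is floored at the contour area so convex masks report exactly zero
concavity. The maximum Feret diameter is the hull diameter (maximum pairwise
vertex distance — identical to rotating calipers over antipodal pairs and
exact for the polygon); the minimum width is the minimum over hull edges of
the extent perpendicular to that edge, exact because a convex polygon's
minimum width is realised flush with an edge. A 0.1°-step brute-force
directional sweep is retained in the tests as an independent oracle.

**Sequence aggregation.** A particle's frames are reduced the way 3D DIA
instruments report: A, P and CH_A as frame means, Feret length F_L as the
max of per-frame maximum Ferets, thickness F_T as the min of per-frame
minimum widths. Whether instruments average CH_A over frames is not
documented; the frame-mean is this package's choice. Shape factors are then
computed from the aggregates (per-frame values remain available through
`measure_projection` for diagnostics):
φ = D_a/D_p, r = 4A/(π F_L²), AR = F_T/F_L, c = (CH_A − A)/CH_A.

Discretisation tolerances: at 0.01 mm/px a radius-100 px disk sequence
yields φ = 0.9985, r = 0.993, AR = 0.996, c = 0.003; errors shrink roughly
linearly with pixel size (`test_disk_descriptors_converge_with_resolution`).
Measured shape factors may exceed 1 by a few tenths of a percent for
near-circular outlines; `ParticleMorphology.validate` therefore allows a 2 %
discretisation slack rather than silently clamping.

**Segmentation.** Components are 8-connected; border-touching components are
measured but flagged, and downstream consumers are expected to exclude them.

## Granulometry

* Classification uses cuts at 0.4 and 3.0 mm with *both boundaries assigned
  to the yield class* ("0.4 up to 3 mm" read as a closed interval). Default
  weights are d³ — sieve mass fractions emulated from image diameters at
  constant granule density.
* The class-histogram mean size is Σ(%·mid-class)/100 over linear bins
  (default width 0.1 mm spanning the observed range, configurable); a
  convergence test verifies the histogram mean approaches the weighted
  sample mean as bins shrink.
* d10/d50/d90 come from the weighted cumulative distribution with the
  midpoint rule and linear interpolation; span = (d90 − d10)/d50;
  d32 = Σnd³/Σnd² on number-weighted diameters. Box-chart statistics (mean,
  sample stdev, 5/25/50/75/95th percentiles) use linear interpolation
  between order statistics and are computed over batch-level values, one per
  run, grouped by impeller speed; a singleton group reports stdev 0 with a
  degeneracy flag.
* Compressibility is CPS = 100·(V₀ − V₁)/V₀ at a recorded applied stress
  (default 15 kPa).

## Response-surface fitting

The six-term quadratic is fitted by OLS in natural (uncoded) units — the
published coefficient magnitudes (e.g. 1.0458×10⁻⁶ on IS²) are only
consistent with actual-unit predictors; a coded-unit helper is provided.
Internally the design matrix is column-normalised before solving and the
scaling undone exactly, because the raw rpm² column degrades conditioning by
~10 orders of magnitude. Noise-free recovery of a known quadratic is exact
to ~10⁻¹⁴ relative.

The ANOVA reports the 5-df Model row and per-term partial (drop-one) sums of
squares — the convention of the DoE software used for the original models —
with sequential (type-I) SS available as an option; p-values come from the F
distribution with (term df, residual df). An exact fit (zero residual SS) is
flagged and reported with infinite F and p = 0 rather than dividing by zero.
The published tables print F to 3–4 significant figures, so internal
consistency (term F = term MS / implied residual MS) is verifiable to 0.1 %
only where 4 figures are printed, and to ~0.5 % elsewhere.

## Pipeline and reproducibility

A single `PipelineConfig` (YAML-loadable) drives simulate → measure →
batch-stats → fit-rsm → report. Every stage writes plain CSV/JSON; mask
stacks are multi-page TIFF or PNG directories. The manifest records the
package version, seeds and SHA-256 of every artifact; reruns with the same
config are byte-identical. Stage failures abort with the stage name. The
RSM stage is skipped (and says so in the manifest) when fewer than 7 runs or
6 distinct design points are available.

Default problem sizes — 5–6 particles × 10 frames at 256² px, 90-run
campaigns, 100–500 granules per batch, 100-replicate coverage simulations —
keep the whole suite and the acceptance script in the tens-of-seconds range
while leaving Monte-Carlo errors well inside the asserted tolerances.

## What the synthetic data do and do not show

Passing tests demonstrate that the measurement chain is correct on shapes
with known geometry and that the statistical machinery recovers known
surfaces under the stated noise. They do not validate the physics of
granulation: the generators contain no nucleation, coalescence or breakage,
no greyscale imaging or segmentation noise, and the lognormal size family
and Gaussian response noise are modelling choices, not measured facts. The
published batch-level measurements (e.g. the box-chart table of the original
study) are consequently *not* reproduction targets; only printed-equation
arithmetic, exact recovery, and geometric identities are.

## Known limitations

* Feret thickness converges to the true minor axis only as the number of
  frames grows; with 10 frames the residual bias is a few percent.
* The perimeter estimator is contour-based; instruments using Crofton-style
  estimators would differ in the third decimal of sphericity.
* The yield refit on clamped noisy data is attenuated near the design
  corners where the reference surface leaves [0, 100] %.
* Sub-pixel measurements assume clean binary masks; no morphological
  cleaning is applied beyond connected-component extraction.
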