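# Methods

This note documents the models, parameter choices and numerical
conventions of the package, and what its synthetic tests do and do not
demonstrate about real mosaics.

## Synthetic scenes

The generator (`smallfield.synthetic`) emulates the structural traits of
smallholder landscapes that drive the method's difficulty, not their
radiometry:

- **Class maps.** Seed points on a jittered grid (cell area = mean field
  area, default 0.5 ha at 4.77 m pixels) are assigned classes by exact
  largest-remainder allocation of the requested mix and grown into
  contiguous patches by nearest-seed labeling through a smoothly warped
  coordinate space. The default mix is the error-adjusted class
  composition of the mapped region (active cropland 16.2%, short fallow
  6.6%, herbaceous 11.2%, open woodland 39.1%, closed woodland 24.0%,
  unvegetated 2.1%, water 0.8%). Realized shares track the request within
  a few percentage points (tested at ±5).
- **Phenology.** No canonical per-class NDVI trajectories exist for the
  region, so the 12-month curves (season-year starting September) are
  free parameters chosen for realistic contrast: cropland shows a
  pronounced wet-season green-up/harvest cycle from a managed, bare
  start; fallows and herbaceous vegetation green up with the rains
  without the management signal; woodlands stay greener with damped
  seasonality; water and bare surfaces are flat. Bands derive from NDVI
  v and a class brightness L as red = L(1−v)/2, nir = L(1+v)/2, so
  rendered NDVI reproduces the trajectory exactly in the noiseless case.
- **Within-field heterogeneity.** A static per-pixel NDVI texture field
  (default SD 0.06, ~1 px correlation length) is added to the land
  surface and warped with it. Unmechanized fields are strongly
  heterogeneous; this texture is also what makes every month correlate
  with its seasonal reference at the true offset, as in real imagery.
  Without it the piecewise-constant class pattern is quasi-periodic and
  correlation matching can lock onto a field-lattice offset.
- **Misregistration** is simulated as low-frequency smooth per-month
  displacement fields (amplitude drawn up to a configurable maximum,
  default 3 px) or explicit constant shifts. **Clouds** are unions of
  random elliptical blobs recorded in the validity mask only; the
  reflectance underneath is untouched because the downstream compositing
  consumes masks. **Terrain** is a smooth ramp-plus-hills surface.
- Per-month white NDVI noise (default SD 0.03) models residual
  atmospheric/BRDF variation.

What passing tests therefore show: the pipeline's stages behave correctly
under known geometry, phenology and contamination. What they do not show:
robustness to real mosaicking artifacts, topographic illumination,
sensor cross-calibration differences, or interpreter label noise.

## Coregistration

- Matching runs on the NIR band only; other bands inherit the field.
- Seasonal references are per-pixel medians of valid NIR observations in
  three 4-month windows; pixels with zero valid observations are flagged
  undefined and filled with the scene mean for correlation only.
- Coarse-to-fine block matching (default block 64 px, 3 pyramid levels;
  the depth is automatically capped so the coarsest level still holds a
  few blocks). At the coarsest level the search radius covers the maximum
  offset (default 100 m = ~21 px); refinement levels search ±6 px.
  Sub-pixel refinement is a 1-D quadratic fit around the integer
  normalized-cross-correlation peak in each axis.
- Blocks with a correlation peak below 0.3, without texture, or whose
  offset deviates from the median confident offset by more than
  3 × 1.4826 × MAD (floor 2 px) are treated as uninformative and inherit
  the smoothed neighborhood estimate via normalized convolution.
- **Stiffness** maps to the standard deviation (in blocks) of the
  Gaussian smoother on the block displacement grid, sigma = 0.4 ×
  stiffness. The mapping is monotone — higher stiffness, smoother field —
  and the default (5 → sigma 2 blocks) strongly suppresses block-to-block
  jitter.
- Offsets are clamped to the maximum offset after every level; warping is
  bilinear for bands and nearest-neighbor for validity masks; a zero
  field is a bit-exact no-op.
- Tiled processing estimates per buffered tile and writes back tile cores
  only; the buffer must cover the maximum offset in pixels so clamped
  offsets never read outside the buffered tile.

Measured on textured synthetic scenes, constant shifts up to ±15 px are
recovered with mean absolute error well below 0.5 px. On scenes with
smooth random per-month jitter (96² px, 20 seeds), coregistering against
the series' own seasonal references reduces mean TSNoise in the large
majority of seeds (paired one-sided Wilcoxon p < 0.05). The reduction is
not universal per pixel: per-pixel TSNoise is itself a noisy statistic,
and interpolation during warping adds a small floor, so the package
asserts the mean contrast (overall and at field-edge pixels) rather than
a per-pixel guarantee.

## Time-series noise

The statistic is implemented as the mean squared deviation of each
interior observation from the linear interpolation of its triplet
endpoints, divided by N−2. The printed form of this statistic is
typographically ambiguous about operator grouping; the implementation
follows the verbal definition (deviation of the center value from the
chord). A square-root variant (NDVI units) is exposed via `root=True`.
Missing months shrink the triplet set — no imputation — and unequal
spacing enters through the month terms. Undefined where fewer than three
valid observations exist.

## Features

- Percentiles use linear interpolation between order statistics (the
  numpy default); the convention is asserted in tests.
- Circular kernel membership: pixel centers within the radius; edge
  pixels use the truncated (in-grid) part of the kernel, implemented as a
  NaN-padded sliding-window nanmedian.
- Contrast indices define 0/0 = 0. For non-negative inputs CI is bounded
  in [−1, 1] and its sign follows P50 − TI.
- Slope is computed by central differences in degrees; coordinate layers
  hold pixel-center coordinates (pixel (0,0) center = origin + half a
  pixel; x east with columns, y north with rows).
- The default stack has 31 named layers (15 seasonal metrics, 6 TI, 6 CI,
  elevation, slope, latitude, longitude) in a fixed order recorded in a
  JSON manifest.

## Active learning

- The classifier contract is any seeded probabilistic multiclass learner;
  the default is a 250-tree random forest. Argmax ties break to the
  lowest class code for deterministic maps.
- Margin thresholds are the class-wise 25th percentile of M_prob over
  pixels predicted as the class; rasters above 10⁶ pixels are subsampled
  reproducibly before the quantile.
- The minimum-distance constraint applies to augmentation samples as well
  as the initial sample (config-toggleable); spreading the low-confidence
  samples across regions avoids wasting the budget on one confused patch.
- Targeted augmentation of a single hard class (the short-fallow case)
  uses the same machinery with a class filter.

The margin-vs-random comparison (`compare_augmentation_strategies`) is a
reduced-scale analog of the two-stage campaign: 96² scenes, 8 initial and
15 augmentation points per class (minimum distance 4 px), 100 trees, and
full-map accuracy over all non-training pixels as the paired score. The
targeted strategy wins at least 80% of 20 seeded replicates with a mean
gain near 2 accuracy points. This demonstrates the qualitative benefit
only; the campaign's reported improvement on real imagery involved
interpreter-guided labeling that a truth-map labeler cannot emulate.

## Validation and area estimation

- Estimators follow the standard stratified design-based formulas
  (area-weighted cell proportions p_ij = W_i n_ij / n_i·; OA, UA, PA,
  area shares as row/column/diagonal functionals; variances
  V(UA_i) = UA_i(1−UA_i)/(n_i·−1),
  V(OA) = Σ W_i² UA_i(1−UA_i)/(n_i·−1),
  V(p_·j) = Σ_i W_i² q_ij(1−q_ij)/(n_i·−1), and the PA variance
  combining commission of the class with omission into it). 95% intervals
  are normal-approximation (1.96 SE).
- A published proportions matrix is ingested as-is: cell sums may deviate
  from 1 by up to 1e−3 (publication rounding) and are renormalized only
  on request, so printed figures reproduce as printed. Quantities that
  are ratios of rounded cells can differ from printed summaries by up to
  ~0.2–0.3 percentage points.
- Unlabelable validation units are excluded without touching the design
  weights. Treating them as their own stratum is a documented alternative,
  not the default.
- Class merging aggregates cells, weights and counts; it can only move
  mass onto the diagonal, so overall accuracy never decreases.
- Simulated coverage of the 95% area CIs (4 strata, 50 samples each,
  1,000 replicates) sits within 5 points of nominal.

## Aggregation

Grid-cell fractions are exact pixel counts; partial edge cells use their
actual pixel counts, so cell-weighted means reproduce the full-map class
shares exactly. The fallow-share curve reports per-bin count, median and
interquartile range of the fallow fraction of total cropland, excluding
cells without cropland; any per-cell covariate (e.g. accessibility) can
be joined by the caller — no external datasets are bundled.

## Pipeline

The end-to-end runner derives all stage seeds from one master seed,
stamps artifacts with a config hash, and logs stages as JSON lines. The
demo configuration used in tests runs a 96² scene with reduced forest
size and sampling floors so the full chain stays fast; the defaults
target 256² scenes. On small maps the validation design is automatically
reduced (floors capped by the rarest stratum, n capped at a quarter of
the map) to keep the stratified draw feasible.

## Known limitations

- The coregistration cannot fix errors at scales below its block grid,
  and textureless regions (water, full cloud) carry interpolated fields.
- Published-matrix mode provides point estimates only; counts are
  required for uncertainty.
- The synthetic labeler is error-free; real interpreter noise and the
  unlabelable fraction of validation units are not simulated.
- Geographic CRS handling is pass-through metadata; all geometry is in
  pixel units with a nominal pixel size.
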