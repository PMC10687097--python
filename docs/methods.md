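# Methods

## The problem

Livestock censuses in extensive rangeland systems are published as district
totals, while ecological and epidemiological questions — grazing pressure,
carrying capacity, zoonosis risk — need per-pixel densities. `gridherd`
implements a settlement-proxy dasymetric workflow for turning a district
census table into annual 1 km density grids:

1. **Pseudo-sampling.** Each district's census density `O_j / A_j`
   (head/km²) is assigned to the district's *k* most populous settlements
   (default k = 10). Covariates are read at the settlement's pixel or
   averaged over a circular buffer (0/2/5/10 km) around it; the buffer
   stands in for the daily movement range of village-housed herds and is
   deliberately not clipped at district borders.
2. **Random-forest disaggregation.** A forest regression `density ~ 13
   covariates` is tuned by repeated k-fold cross-validation over
   (mtry, ntree), fitted on the training partition, and applied to the
   covariate rasters to predict every pixel.
3. **Mass-conserving adjustment.** Within each district the predicted
   pixels are rescaled by `O_j / P_j` (observed over predicted district
   totals in heads), so the grid reproduces the census exactly
   (pycnophylactic property) while keeping the predicted within-district
   pattern.
4. **Trend detection.** Per-pixel Mann-Kendall (tau-b, tie-corrected
   variance, continuity-corrected normal deviate) and Sen's slope over the
   adjusted annual stack, masked at raw p < 0.05.

## Model-selection experiment

Twelve candidate designs — four buffer radii × three train:test splits
(70:30, 80:20, 90:10) — are each independently tuned, fitted and scored
with CV and independent-test R²/RMSE/MAE. A design is selected for having
*jointly* low errors and high R² on both scores: each of the six metrics
ranks the twelve cells and the lowest mean rank wins (ties resolve toward
the larger buffer, then the larger training fraction). A single-metric
argmin (e.g. test RMSE alone) is deliberately not used: with ~12-24
district-level response values per test fold, single test metrics are noisy
enough to invert the ordering between otherwise-equivalent designs, while
the rank ensemble is stable. Replaying the published Kazakhstan
small-ruminant selection table through this rule returns the 10 km buffer
with the 90:10 split (`gridherd.reference.published_selection_table`).

The chosen (buffer, split) is held fixed across years; forests are refitted
(optionally re-tuned) independently per species-year.

## Synthetic landscape generator

All tests run against a fully synthetic region whose statistical structure
matches what the workflow assumes:

- **Districts**: Voronoi cells of uniformly random seed pixels — contiguous
  zones with realistic size variation.
- **Settlements**: Gaussian scatter around each district centroid
  (sd = 1/4 of the district's equivalent radius, resampled until inside);
  populations log-normal (median 500, sigma 1.2), spanning hamlets to
  cities.
- **Covariates** (13): the climate-like layers (precipitation, temperature,
  vapour-pressure deficit, solar radiation, soil moisture, snow depth, LAI,
  NPP) are unit-variance Gaussian random fields smoothed at a 10 km length
  scale, built as a static spatial climatology plus a 0.3-weighted
  interannual anomaly redrawn each year — annual climate surfaces are
  dominated by stable geography, and a generator with fully independent
  annual fields would make the density's climate drivers unobservable
  outside the base year. Elevation is a static smoothed field plus a linear
  gradient; population density and nighttime light are sums of
  per-settlement Gaussian kernels (3 km and 5 km bandwidths) scaled by
  population; distance-to-settlement and distance-to-water are exact
  Euclidean distance transforms (pixel-center metric, km).
- **Latent truth**: `D0 = c · exp(Σ β_k z_k) · exp(−d_settle / 10 km)`,
  with z-scores saturated at ±3 sd (without saturation a handful of
  city-kernel pixels carry densities thousands of times the regional mean,
  outside the dynamic range real density maps show). Default β: population
  density 0.8, temperature 0.5, precipitation 0.3. Year *t* adds a relative
  linear trend `(1 + 0.02 t)` and additive Gaussian noise (sd 2 head/km²
  for small ruminants, scaled down with the mean for horses), clipped at
  zero (the clipping rate is logged). The surface is normalized to a mean
  of 20 head/km² (small ruminants) / 2 (horses).
- **Census**: exact aggregation of the truth (density × pixel area summed
  per district), so the downscaling target is internally consistent.

Reference configuration: 24 districts on a 200×200 grid of 1 km cells, 12
settlements per district, 20 years (2000–2019), seed 42.

What the generator does *not* emulate: physical units or cross-correlations
among covariates (fields are mutually independent apart from the
settlement-derived ones), seasonal structure, transhumance, or
administrative boundary changes. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under the assumed
structure, not performance on real rasters.

## Numerical choices

- **Distances** are between pixel centers, in km via the cell size; a point
  source snaps to its containing pixel. `scipy.ndimage.distance_transform_edt`
  is the engine; tests verify equality with brute-force min-over-sources.
- **Adjustment degeneracies**: `O_j = 0` zeroes the district; `P_j = 0`
  with `O_j > 0` (ratio undefined) falls back to uniform allocation over
  the district and flags it. Conservation is asserted at 1e-9 relative.
- **Mann-Kendall**: tau-b with tie-corrected variance (annual density
  rasters tie at zero-density pixels); normal approximation with continuity
  correction — accurate for the 20-year series the pipeline targets, so no
  exact small-n tables. No multiple-testing correction by default (trend
  maps are conventionally masked at raw p < 0.05); Benjamini-Hochberg is
  available behind a flag. Trends run on adjusted surfaces (the published
  product); a switch selects raw predictions instead.
- **Splits**: point-level by default (replicating the published design);
  district-level grouping is offered because ten identical responses per
  district leak between partitions and flatter the test scores — a caveat,
  not the default.
- **Interpolation** of census gaps is linear in headcounts between flanking
  observed years, real-valued, never extrapolated.
- **Tuning grid defaults** are mtry ∈ {2,4,7,13} × ntree ∈ {250,500} with
  10-fold × 5-repeat CV. The orchestrated `run_pipeline` defaults to a
  reduced search (mtry {4,13} × ntree {200}, 5-fold × 2-repeat, fixed
  ntree = 150 refits per year): on the reference landscape the conservation,
  counting and recovery behaviour is insensitive to tuning depth, and the
  reduced search keeps a full 2-species × 20-year run around a minute.

## Known limitations

- Pixel-level recovery of the latent truth is structurally bounded: all
  training responses are district-constant and observed only at
  settlements, so the forest cannot learn the within-district
  distance-decay beyond the covariate range seen at settlements (forests do
  not extrapolate). On the reference landscape the adjusted surface
  recovers district totals exactly (between-district rank correlation 1.0)
  but the overall pixel-level Spearman correlation with the latent truth is
  ~0.41-0.47, with a noise ceiling of ~0.95 — the gap is the
  settlement-proxy design itself, which is also why pixel-level validity
  far from settlements cannot be claimed for real products built this way.
- The held-out test scores (R² ≈ 0.78-0.94 on the reference landscape)
  measure performance *at settlement points with district-level responses*,
  not per-pixel accuracy; the two can diverge arbitrarily.
- Buffers use Euclidean discs; no road-network or cost distances.
- The generator's covariates are mutually independent random fields; real
  covariate suites are strongly collinear, which changes variable-importance
  attribution (though not conservation or trend behaviour).
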