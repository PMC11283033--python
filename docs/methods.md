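# Methods

## Scope and data model

The pipeline maps invasion risk as the product of an environmental
suitability surface and a human introduction-pressure surface, summarized
over protected-area polygons. All gridded data are single-band rasters on a
plain longitude/latitude grid, exchanged as ESRI ASCII grids; nodata cells
are NaN internally and the header sentinel on disk. Cells are half-open
intervals `[x0+j·s, x0+(j+1)·s)`, indexed row-major from the lower-left
origin; points exactly on the top/right extent boundary belong to the last
cell. Metric distances (focal density, kernel density) are planar, with one
degree of latitude fixed at 111 194.93 m and longitude degrees scaled by
cos(latitude) of the evaluation row; at the sub-kilometer to few-kilometer
radii involved, the error versus geodesic distance is far below a cell.

## Occurrence handling

`clean_records` applies four filters in a fixed order — missing
coordinates, observation year before a cutoff (default 2000), coordinate
uncertainty above a maximum (default 10 000 m), exact coordinate duplicates
(first kept) — and logs each removal count into the set's provenance.
Records with a *missing* year or uncertainty are kept: absence of metadata
is not treated as disqualifying. The uncertainty filter is configurable
because source metadata conventions vary; 10 km is one order above the
analysis resolution (~1 km cells) and removes records that could not be
assigned to a cell neighborhood meaningfully.

`thin_to_grid` keeps one record per occupied cell, chosen uniformly with a
seeded RNG, and orders output by row-major cell index so the result is a
pure function of the input set and seed. Thinning is idempotent, and the
set of occupied cells is invariant under input permutation (only the choice
of representative may change).

## Predictor preprocessing

* **Organic soils**: a percentage raster is binarized at an inclusive
  threshold (default 50 %), then `focal_density` replaces each cell by the
  fraction of valid cells within a metric radius (default 500 m) that are
  1. The density is a dimensionless fraction in [0, 1] rather than a count
  per area — only relative values matter downstream. Real multi-class soil
  products should be unioned to a single percentage raster before entry.
* **Resampling** supports nearest, bilinear (valid-neighbor weighted) and
  mean-aggregate (any contributing nodata → nodata) onto an arbitrary
  target header. Density is computed at source resolution and resampled
  afterwards; the order is exposed to callers who need the opposite.
* **Correlation pruning** computes pairwise Pearson correlations on a
  seeded random sample of jointly valid cells (default 10 000) — i.e. over
  the calibration area as surfaces, not at occurrence sites — then greedily
  removes, from the worst pair, the variable with the larger mean absolute
  correlation to the rest (alphabetical tie-break), until all pairwise
  |r| ≤ 0.7. Removal triggers strictly above the threshold; a 1e−10
  absolute tolerance keeps a pair at exactly the printed threshold intact
  under floating-point rounding. Zero-variance layers get zero correlations
  and a warning rather than an error.

## Suitability model

The model is the Gibbs distribution over background cells described in the
README. Numerical choices:

* **Features** are rescaled to [0, 1] by their training min/max; hinge
  features use evenly spaced interior knots (default 5 per variable, both
  orientations). Constant variables retain only their degenerate linear
  feature. The default class schedule follows presence count: ≥ 80
  presences → linear+quadratic+product+hinge; ≥ 15 → linear+quadratic+
  hinge; ≥ 10 → linear+quadratic; otherwise linear. Tests and the
  recovery studies restrict to linear (and quadratic) classes to keep the
  estimand interpretable.
* **Regularization**: per-feature λⱼ = multiplier × r_class(m) ×
  max(sd_presence(fⱼ), 0.01) / √m, with r_class interpolated on the
  canonical per-class sample-size tables (linear 1→0.05 over m = 0→100;
  quadratic 1.3→0.25; product 2.6→0.43; hinge 0.5). A single multiplier
  (default 1.0) scales all of them.
* **Optimizer**: proximal Newton from β = 0. Each outer iteration forms
  the exact gradient (presence means minus model expectations) and Hessian
  (feature covariance under the model, plus a 1e−9 ridge), solves the
  L1-penalized quadratic subproblem by cyclic soft-threshold coordinate
  descent, and backtracks on the exact penalized objective. Convergence is
  declared at relative objective change < 1e−10 (or a verified stationary
  point); failure to converge raises, reporting the last objective gap.
  The method is deterministic — no seed — and its quadratic local
  convergence leaves moment-matching gaps orders of magnitude below the
  1e−6 level the tests assert. Soft-thresholding yields exact zeros under
  strong penalties.
* **Prediction**: inputs are clamped to each variable's training range
  before feature evaluation; raw output is exp(η − log Z) (summing to 1
  over the training background) and cloglog output is
  1 − exp(−e^H · raw), H being the entropy of the fitted background
  distribution.
* **Evaluation**: AUC is the rank-based Mann–Whitney statistic with
  midrank ties. k-fold cross-validation (default k = 10) splits presences
  by a seeded permutation into near-equal folds, fits on the remainder
  against the full background, and scores held-out presences versus the
  background; the final map is the per-cell mean (and sd) of the k fold
  models' cloglog predictions. Presences are appended, flagged, to the
  background sample (up to 10 000 uniformly drawn distinct valid cells),
  the standard convention that the background represents the available
  environment; importance is computed on an all-data fit.
* **Permutation importance** shuffles one source variable jointly across
  presence and background rows (seeded, averaged over repeats, default 3),
  re-evaluates features, and records the AUC drop clipped at zero (a
  shuffle can spuriously raise AUC); drops are normalized to percentages
  summing to 100, or all-zero with a warning when nothing drops.
* **Response curves** sweep one variable across its training range with all
  others fixed at their training means.

## Introduction pressure and risk

Store density uses the quartic (biweight) kernel of planar GIS density
tools, `3/(πh²)·(1−(d/h)²)²` for d < h, in points per m². The default
bandwidth is the Silverman-style GIS rule
`h = 0.9·min(SD, √(1/ln 2)·Dm)·n^−0.2` (SD the standard distance about the
mean center, Dm the median distance to it), always logged so a run's
bandwidth is on record; it can be overridden. The finite support makes the
surface integrate to the point count when no point lies within h of the
boundary — the package's mass-conservation check. The density is then
min–max normalized to [0, 1] (a constant surface is an error, since its
normalization is undefined), multiplied cellwise with mean suitability, and
summarized per polygon by cell-center containment: mean, max, fraction of
cells at or above a hotspot threshold (default 0.5 — a reporting parameter,
not an ecological constant), and cell count. Polygons covering no valid
cell are flagged, not dropped.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
any real geography:

* **Predictors** are white noise smoothed by a square moving-average window
  (side = autocorrelation range in cells; 1 = no smoothing), standardized,
  and mapped to plausible ranges (a temperature-like band, mean 15 °C,
  sd 5; a precipitation-like band, mean 800 mm, sd 250, floored at 0;
  further bands standardized; an optional organic-matter band as a logistic
  squash to [0, 100] %). Default grid: 0.01° cells anchored near 39° N.
* **Truth**: η = Σ βⱼ zⱼ with zⱼ the grid-standardized predictors; |β|
  drawn uniformly in [0.5, 1] × scale (default 1.5) with random sign, and a
  stated fraction (default 1/2) set exactly to zero so pruning and
  importance have known-irrelevant variables.
* **Presences** are cells drawn with replacement ∝ exp(η), jittered
  uniformly within the cell (sub-cell position carries no signal at the
  analysis resolution). Years are uniform on 1995–2023 and coordinate
  uncertainties log-uniform on 10–30 000 m, deliberately straddling the
  default cleaning cutoffs so the cleaning stage has realistic work.
* **Stores** are Gaussian clusters (centers uniform over the extent;
  out-of-extent draws resampled); **protected areas** are random
  axis-aligned rectangles of ≥ 4 cells with alternating RNAP/RN2000 tags.

What passing tests on these data do *not* show: robustness to real-world
sampling bias correlated with predictors, non-log-linear responses,
coastline/land-mask effects, CRS reprojection, or observer error beyond
the modeled uncertainty field.

## Pipeline and reproducibility

`run(config, outdir)` executes clean → thin → prep → prune → background →
k-fold fit/evaluate → ensemble predict → importance → KDE → normalize →
combine → zonal, writing every intermediate product plus a JSON manifest
(config echo, per-stage seeds, counts, timings). Each stage's seed is
`(global_seed XOR crc32(stage_name)) mod 2³¹`, so stage streams are
independent and reruns are bit-identical. Any stage failure aborts with the
stage name after writing the manifest accumulated so far.

## Verification problem sizes

The verification suite runs small by design: optimizer-oracle comparisons
on ≤ 30×30-cell backgrounds with ≤ 5 linear features; parameter recovery on
a 100×100 landscape with 500 presences (3 informative + 3 null
predictors); null-truth calibration at 200 presences; importance ranking
over 50 simulated 25×25 landscapes; pruning over 100 random 5-variable
fixtures; and the full pipeline on a 50×50 simulated landscape run twice
for bit-identity. These sizes make every property cheap to recompute while
leaving the estimators well inside their asymptotic regimes.

## Known limitations

* No CRS handling beyond plain geographic grids; no GeoTIFF/multi-band I/O.
* The focal and kernel distance model is planar with per-row scaling —
  appropriate at sub-kilometer to few-kilometer scales, not for
  continental-radius kernels or high latitudes.
* Hinge-heavy models with many knots make the dense Hessian of the
  proximal-Newton step the memory/time bottleneck; the default knot count
  keeps this small.
* Threshold-based binary maps, jackknife analyses, MESS/novelty maps and
  climate-change projections are out of scope.
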