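# Methods

## Model and procedure

`habsuit` implements a presence-background species distribution modelling
workflow in two presets. The `original` preset fits a downsampled random
forest, a depth-2 shallow random forest, boosted regression trees and a
MaxEnt-style model on terrain, precipitation and geology covariates, and
ensembles the three tree-based models; the `final` preset adds a soil color
index covariate and true-absence points from field-survey cells, swaps the
shallow forest for MARS and a GAM, and includes all five models in the
ensemble. Ensemble weights are each member's validation AUC-PR divided by
the included members' AUC-PR sum, so the ensemble is a convex combination
of member suitability scores and always lies inside their hull.

Underlying assumptions worth stating: occurrences are treated as an
unbiased (if thinned) sample of occupied habitat; background points stand
in for availability, not absence; undetected surveyed cells are treated as
true absences — imperfect detection is not modelled; all layers live in one
projected CRS with meter units, and geographic (degree) inputs are rejected
rather than reprojected so distance arithmetic stays exact.

## Covariates

- Slope/aspect use Horn's 3×3 finite differences with edge replication at
  the raster border; slope is arctan of the gradient magnitude in degrees.
  Aspect is the compass direction of the downslope vector (clockwise from
  north), chosen so north-facing cells get northness +1; flat cells, where
  aspect is undefined, get northness = eastness = 0 so they contribute no
  directional signal (rather than nodata, which would drop the cell).
- Geology is an ordinal class raster (1–4) from the Euclidean cell-center
  distance to the nearest formation cell, binned at 1, 10 and 100 m. It is
  carried as a numeric feature; the distance metric is planar, justified by
  the projected-meters contract.
- Precipitation is stored in millimeters and resampled to the base grid by
  cell-center bilinear interpolation of the four nearest coarse centers,
  with edge-value extension between the coarse center hull and the coarse
  footprint. Continuous layers are resampled bilinearly; masks and class
  rasters only ever nearest-neighbor (categorical integrity).
- Covariate extraction at points is a containing-cell lookup; at the
  resolutions used here the difference from bilinear extraction is far
  below the noise floor, and the rule keeps class layers exact. Points
  outside the extent or on nodata are excluded and reported with a reason.

## Occurrence engineering

Distance filters implement "no points closer than d" as a greedy sequential
scan in input order: a point is kept iff it is ≥ d from every already-kept
point, with ties at exactly d kept. Greedy scanning is deterministic and
order-stable; since the original field data's processing order is unknown,
the choice is a convention, not a claim.

Polygon-derived presences: polygons under 20 m² contribute their centroid;
larger ones are rasterized on a 10-m grid (a cell is covered iff its center
lies inside, which guarantees the two rules never both apply) and
contribute covered-cell centroids; slivers ≥ 20 m² covering no center fall
back to the centroid. The combined polygon-derived candidates are thinned
to ≥ 40 m as one set, so two polygons closer than 40 m may end up sharing a
representative — the per-polygon ≥1-point guarantee holds for the candidate
set before thinning. Merged presences (point observations + polygon points)
are thinned to ≥ 2 m; background and absence candidates strictly closer
than 100 m to a presence are removed in the final preset only (the original
preset deliberately leaves background unfiltered). The final preset tops up
background counts to preserve the original presence:(background+absence)
ratio so AUC-PR is comparable between presets. The train/validation split
is per-label (stratified) at a 2/3 fraction, seeded; stratification is
adopted as the safer reading of "split both the presence and background
points".

## Models

All six algorithms share one contract (scores in [0, 1]; stateless,
deterministic prediction; dense importance ranks with unused covariates
unranked). Defaults, overridable per model:

| model | defaults |
|---|---|
| rf_downsampled | 500 trees, √k features per split, per-tree balanced bootstrap (equal presence/background counts, sampled with replacement) |
| rf_shallow | 500 trees, max depth 2 |
| brt | 1000 trees, learning rate 0.01, depth 3, bag fraction 0.5 |
| maxent | ℓ1-regularized logistic (C = 1) on standardized linear + quadratic + pairwise-product features; probability output |
| mars | ≤15 terms, interaction degree ≤2, 10 quantile knots per variable, GCV pruning penalty 3 |
| gam | penalized B-splines, df 5, degree 3, α = 1 per smooth |

Numerical choices: the MARS forward pass selects hinge pairs by exact
least-squares RSS through normal equations with a 10⁻⁹ ridge; backward
pruning minimizes GCV with effective parameters m + 3(m−1)/2. The GAM
response is lightly label-smoothed (ε = 10⁻³) and the penalty escalated
(×100, ×10⁴) if the binomial IRLS hits perfect separation — steep synthetic
truths make separation a real occurrence; prediction inputs are clipped to
the training hull because B-spline bases do not extrapolate. MaxEnt-style
output is the logistic probability (the classical tool's output transform
is a presentation choice; ranking metrics are unaffected). Tree models are
bit-reproducible under a fixed seed; spline/additive fits are deterministic
given the data.

Variable importance is algorithm-native: mean impurity decrease for the
tree models, summed |coefficient| over derived features for the
maxent-style model, forward-pass RSS-reduction attribution over retained
terms for MARS (covariates in no retained term are unranked), and the
variance of each smooth's partial prediction for the GAM.

## Metrics, ensemble, threshold

AUC-ROC is the midrank Mann–Whitney statistic; AUC-PR is the
average-precision step estimator with tied scores grouped — trapezoidal
interpolation in PR space is optimistic and is not used. The normalized
average min-max scales each metric column across the whole table including
the ensemble row (required for the published table arithmetic to
reproduce), mapping a zero-range column to 0.5 for every model so an
uninformative metric is neutral.

The fixed-sensitivity threshold searches only achievable cutoffs (observed
scores plus 0 and 1) for the largest t with sensitivity ≥ the target
(default 0.95), with classification score ≥ t — ties suitable, the
conservative direction for a rare species. The threshold is chosen on the
ensemble's *training* presence scores (the source point set is a free
choice; training scores keep validation data untouched). Area accounting
uses 247.10538 acres/km², rounding acres to integers for reporting. A
maximum-sensitivity-plus-specificity cutoff is available as an alternative
but is not the default.

## Field validation

Per-cell suitability is the mean of valid prediction cells inside each
50-m square (max and center-cell are options). Cliff's delta is computed
exactly via midranks (equivalent to all-pairs enumeration). The one-sided
Wilcoxon rank-sum test uses exact enumeration for small tie-free samples
and the tie-corrected normal approximation otherwise (scipy's automatic
policy, which includes a continuity correction — slightly conservative, as
the type-I simulation in the test suite shows). The 2×2 contingency test is
Pearson χ² without continuity correction, with Fisher's exact test offered
when any expected count falls below 5; Cramér's V reduces to √(χ²/n) for a
2×2 table.

## Synthetic landscape: what it emulates, and what it does not

The generator reproduces the *shape* of the study system: a fine DEM
(smoothed Gaussian random field with controllable relief amplitude and
roughness, plus an optional planar trend), a minority geologic formation
(buffered-random-walk blobs whose cell-center mask is consistent with the
polygons by construction; only the masked fraction ±20 % is contractual), a
coarse 800-m precipitation gradient running 220→320 mm north to south,
spectral bands whose soil color index is elevated on the formation,
presences sampled with probability proportional to a known logistic
suitability (point observations plus buffered-disk subpopulation polygons
seeded in the top suitability quintile), and 50-m survey cells with
Bernoulli detections whose default probability is the cell's mean true
suitability clipped to [0.01, 0.99] so both outcomes occur. Cell placement
is a policy knob (uniform or suitability-weighted) because the original
survey's placement rule is undocumented. All stages draw from named
substreams of one master seed, so regenerating one layer never perturbs
another.

It does **not** emulate: LiDAR sensor artifacts, real geologic geometry,
atmospheric effects in the spectral bands, observation bias in occurrence
records, spatial autocorrelation between survey cells and training
presences, or imperfect detection. Passing tests therefore demonstrate
that the pipeline recovers a known signal under clean conditions — not
that any particular real-world map is accurate.

Default workflow problem sizes are deliberately compact: a 300×300-cell
landscape at 10-m cells (3 km × 3 km — large enough that the 100-m
exclusion rule leaves background area), ~400 point observations, a handful
of subpopulation polygons, a few thousand background points, and tens of
survey cells. The 10-m synthetic cell size is a scaled stand-in for the
1-m grids the method targets; every grid operation is resolution-agnostic.

## Known limitations

- No spatial cross-validation; the random split can flatter models when
  occurrences are spatially clustered (the field-validation statistics are
  the intended antidote, and are themselves optimistic when survey cells
  sit near training presences).
- The MaxEnt realization is a regularized logistic approximation, not the
  legacy implementation; absolute score calibration differs even where
  ranking agrees.
- No probability calibration and no uncertainty layer beyond the ensemble
  spread; the ensemble raster is a point estimate.
- Ordinal geology enters models as a numeric feature (a one-hot encoding
  is available at extraction time but is not the default).
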