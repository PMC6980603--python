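# Methods

## The model

The response is binary: did a turbine location ever yield a carcass
detection of the target species (presence) or only detections of other
bird groups (pseudo-absence)? The predictors are the 12 signed
distance-to-edge land-use variables (DELVs) sampled at the turbine's
grid cell. The fitted object is a boosted regression tree (BRT)
ensemble with logit link and Bernoulli deviance

    D(y, p) = -2 mean( y log p + (1 - y) log(1 - p) ),

built forward-stagewise: the intercept is the empirical log-odds, and
each iteration fits a shallow regression tree to the current negative
gradient (y − p) on a random bag of rows, adding it scaled by the
learning rate. Terminal node values are the one-step Newton estimate
Σ(y−p) / Σ p(1−p) over in-node bagged rows, clipped to ±4 to guard
degenerate nodes; a node whose residuals are exactly zero gets value 0.

Assumptions worth keeping in mind: detections are treated as
exchangeable across turbines (no search-effort, persistence or
detectability model); the landscape is static; one cell value (the
nearest-cell rule) represents a turbine's context, so sub-cell position
is ignored at the 100 m resolution.

## DELV construction

Class polygons are unioned per class (class semantics, not feature
semantics), their boundaries rasterized onto the analysis grid: a cell
is an *edge cell* when the boundary polyline intersects its square.
Every cell then receives the Euclidean distance from its center to the
nearest edge-cell center (scipy's exact distance transform), negative
when the cell center lies inside the class and the cell is not itself
an edge cell. Distances are center-to-center on the rasterized edge
set rather than to the exact vector geometry — consistent with a
raster workflow at 100 m and exactly reproducible by a brute-force
scan, which the test suite uses as an oracle. Cell centers that fall
exactly on a polygon boundary count as inside; the choice is a
deterministic tie rule with no numeric consequence because edge cells
are zero anyway.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| cell_size | 100 m | raster resolution of all surfaces |
| tc | 12 | splits per tree; ties the interaction order to the predictor count, and backward simplification shrinks it with the retained set |
| lr | 0.005 | shrinkage per tree when fitting at fixed nt |
| bf | 0.5 | bag fraction drawn without replacement per tree |
| lr ladder | 0.05 … 0.0005 | descending candidates for the stepped scan |
| step_size | 50 trees | granularity of the cross-validated scan |
| min_trees | 1000 | a learning rate is accepted only when the selected ensemble holds at least this many trees |
| k_folds | 10 | folds, stratified by label, frozen once per scan |
| min_node | 10 rows | minimum terminal-node size |
| patience | 6 steps | scan stops after 300 trees without CV improvement |
| balance ratio | 1:1 | presences vs pseudo-absences after down-sampling |
| BPDmax | 51 | lower border of the highest breeding-pair class |

The tree-number selection mirrors the stepped procedure of the R
`dismo::gbm.step` tradition: grow all fold models `step_size` trees at
a time, evaluate the pooled cross-validated predicted deviance after
each step, take nt at the curve minimum, and walk down the learning
rate ladder until nt ≥ 1000. If even the smallest rate falls short the
scan returns it with a warning rather than failing. The final model is
refitted on the full training data at the selected (lr, nt).

## Interpretation statistics

*Relative influence* sums the squared-error improvement of every split
per variable over the used trees and normalizes to percentages (sums
to 100 by construction). *Partial dependence* sweeps one variable over
100 equally spaced training quantiles while averaging predictions over
the training rows, on the link scale. The *pairwise interaction size*
evaluates the two-variable partial-dependence surface on a 15 × 15
quantile lattice, removes the best additive (row + column) fit — the
two-way mean decomposition, which is the exact least-squares solution —
and reports 1000 × the mean squared residual. The scaling puts typical
values in the same order of magnitude as published interaction sizes
for this model family, but the statistic is not numerically identical
to any particular R implementation; it is exactly zero for additive
ensembles and symmetric by construction.

*Evaluation* reports the rank-statistic AUC (ties counted half), and
sensitivity/1-specificity at a threshold chosen by the Youden rule
(max sensitivity + specificity − 1) unless a fixed threshold is given;
published tables for such models imply an unstated threshold, so the
rule is configurable. Cross-validated deviance explained, CVdev =
100 · (null − CV deviance)/null, is reported with a fold-wise standard
error; the CV AUC is reported both fold-averaged and pooled, since
published values do not say which convention they use.

## The synthetic landscape generator

The generator emulates the structure of a state-wide biotope map
without reproducing any real geography. A capacity-constrained,
seeded, multi-source region-growing process assigns every 100 m cell
to exactly one of the 12 classes: integer cell quotas per class follow
the published coverage fractions (largest-remainder rounding,
renormalised so the classes partition the region), each class plants
seeds proportional to its quota over its characteristic patch area,
and classes claim nearest frontier cells in round-robin order with
random jitter. Realized coverages therefore match the targets exactly
up to rounding, and patches are contiguous and organic-looking.
Per-class patch scales default to large blocks for fields/forests
(2 km) and small scattered patches (300–500 m) for rare linear-ish
classes (watercourses, bushes, shrubs, ruderal areas), so that turbine
distances to rare-class edges straddle the kilometre-scale thresholds
of the risk surface instead of collapsing into "far away" for every
turbine.

The default generative risk surface mirrors the four headline drivers:
risk rises beyond 1000 m from flowing-watercourse edges, beyond 750 m
from grass/forb edges, inside the 750–1750 m band around green areas
near settlements, and beyond 1500 m from bushland edges. Each effect
is a centred piecewise-linear smooth step of 3 log-odds total swing
(±1.5). This amplitude is a deliberate calibration: it gives the
simulation an information content (AUC of the true probabilities
≈ 0.90) such that a well-fitted model lands in the 0.85–0.90 holdout
range typical of published carcass-based collision models, leaving
headroom for the recovery tests without making the signal trivially
strong. Breeding-pair density quadrants default to 5 km (a map-sheet
scale tiling) with class probabilities centred on the 8–20 and 21–50
BP classes, the modal classes of regional atlases.

What the generator does **not** emulate: search-effort heterogeneity,
carcass persistence and detection bias (acknowledged but unquantified
in field data — no bias structure is invented), spatial correlation of
monitoring, linear (polyline) watercourse geometry, and temporal
dynamics. Passing recovery tests therefore show that the estimator
chain is correct and well calibrated under clean exchangeable
sampling, not that field data of this kind are free of those biases.

## Numerical choices

- Split search is exhaustive over midpoints of sorted unique values,
  vectorized across features; ties break to the lowest variable index,
  then the lowest threshold, so fits are bit-reproducible.
- Probabilities at or beyond {0, 1} entering the deviance are clamped
  to 1e-12 with a warning.
- Fold assignment, bagging and all generators use seeded
  `numpy.random.default_rng` streams; a single pipeline seed fans out
  to stage seeds by fixed offsets, and two runs with the same
  configuration are byte-identical.
- SC classes use lower-open bins (0–20], (20–40], … so the bins are
  exhaustive and disjoint; zone-table percentages are truncated (not
  rounded) to two decimals, reproducing the convention of published
  zone tables (e.g. 4/1343 → 0.29). Note that published tables are not
  always self-consistent under either convention (3/929 prints as
  0.33 in one source but truncates to 0.32; the package reports its
  own arithmetic).
- Cells not covered by any density quadrant get BPDrel = 0, hence
  SC = 0: no recorded breeding pairs, no susceptibility claim.
- Rasters are written as single-band float32 GeoTIFFs with pixel-scale
  and tiepoint tags (planar metres, no named CRS).

## Problem sizes in the test suite

The suite exercises the full chain at desk scale, chosen to keep a
complete run near ten minutes: landscapes of 60×60 to 200×200 cells,
2200 simulated turbines, balanced training sets of 300–400 rows with
independent balanced holdouts of 400 rows, ten seeded replicates for
the recovery experiments, and a shortened learning-rate ladder for the
end-to-end determinism runs. The acceptance script runs the full
ladder (10-fold CV, simplification by two predictors) once on a
400-row training set.

## Known limitations

- The interaction statistic's absolute scale is implementation-defined
  (see above); compare interaction sizes within a model, not across
  packages.
- The real study region's fitted values (variable contributions, AUCs,
  tree counts) are not reproducible here because the underlying
  carcass/turbine/biotope data are not deposited; all quantitative
  tests run against synthetic ground truth.
- `gbm_step` evaluates the pooled CV deviance, not a fold-averaged
  one; with stratified equal-size folds the difference is negligible.
- Distances are center-to-center on the rasterized edge set; sub-cell
  vector accuracy is out of scope.
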