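# Methods notes

## Scope and shape

The package models landscape connectivity for a multi-species
assemblage between two terminal reserves on a shared raster lattice.
The core chain is: per-species ensemble suitability → resistance
surface (linear or non-linear scaling) → least-cost and circuit-theory
connectivity → cross-species comparison. The ensemble suitability
model is an sklearn-style estimator (`EnsembleSuitabilityModel`) so it
composes with sklearn pipelines and model selection; resistance
scaling is likewise available as a stateless transformer
(`ResistanceScaler`). The graph solvers and comparison statistics are
plain functions: they have no fit/predict structure to express.

## Grid conventions

One convention, used everywhere: rasters are row-major from the
top-left, x increases east, y increases north, and `origin_x/origin_y`
name the lower-left corner. Cells are square and all rasters in one
analysis must share shape, origin and cell size; alignment and
reprojection are upstream concerns (only validation is provided).
Rasters are stored as ESRI ASCII grids — a plain-text format that
round-trips float32 exactly with nine-significant-digit rendering.
Masks are 0/1 byte rasters; nodata cells use the `-9999` sentinel.

## Suitability modelling

- **Pseudo-absences**: uniform draws without replacement over valid
  cells not containing a presence. Default strategy `random_equal`
  (as many absences as presences), the common choice for tree/ML
  learners; `random` with a larger background *n* (e.g. 1000) suits
  regression-family learners.
- **Geographic thinning**: seeded greedy shuffle; a point is kept iff
  no kept point lies within `min_distance` (default one cell size,
  1000 m). The output satisfies the minimum-distance property exactly;
  the greedy order makes the result seed-dependent, which mirrors the
  arbitrariness of any thinning and is why the seed is recorded.
- **Collinearity screen**: all pairwise Pearson correlations over
  jointly valid cells, flagged above |r| = 0.7. Reporting only — layers
  are never dropped automatically.
- **Learner registry**: four families (logistic regression,
  gradient-boosted trees, random forest, and a quadratic-feature
  logistic model as the exponential-family stand-in for maxent). The
  registry is a plain dict and extensible; four families keep the
  ensemble contract testable without exotic dependencies.
- **Retention and weighting**: per family, `reps` (default 10)
  stratified 70/30 holdout splits; retain if mean holdout AUC ≥
  `retention_auc` (default 0.90, appropriate for strongly structured
  field data; synthetic landscapes with weak effects warrant a lower
  threshold, and the error raised when nothing is retained says so).
  Retained families are refit on all data and weighted by mean AUC
  (uniform weighting available). Stratified splits preserve the class
  ratio and prevent degenerate one-class evaluation sets.
- **AUC** is rank-based (Mann–Whitney), ties counting one half, so it
  is invariant to strictly monotone transforms of the scores.
- **Predictor contributions**: permutation importance — the drop in
  training-data AUC when one predictor's column is shuffled —
  ensemble-weighted, floored at zero and normalized to sum to 100.
- **Stacking**: cell-wise sum of per-species maps, range [0, S];
  nodata propagates. Before resistance scaling the stack is divided by
  S, the only rescaling that keeps the 1-to-101 cost anchors of the
  linear transform meaningful for the multi-species surface.

## Resistance scaling

Linear: `cost = (1 − HS)·100 + 1` (cost-weighted km per km), range
[1, 101]; non-linear: its square, range [1, 10201]. Both are strictly
decreasing in suitability and therefore rank cells identically;
choosing between them expresses how sharply movement cost should rise
in poor habitat. Nodata cells are infinitely resistant: they are
simply absent from the movement graph.

## Connectivity

- **Graph**: 8-connected by default (4-connected optional); edge cost
  between neighbouring cells = mean of their resistances × step length
  (cell km; ×√2 for diagonals). Each terminal reserve is contracted to
  a supernode, so reserves act as endpoints and contribute no internal
  traversal cost. Parallel edges created by contraction coalesce by
  minimum cost for shortest paths and by summed conductance for the
  circuit — the physically correct rule in each case.
- **Least-cost**: exact Dijkstra (scipy.sparse.csgraph) from each
  supernode. `NLCC = CWD_A + CWD_B − LCP`; zero along every optimal
  path. The sliced corridor keeps the lowest `slice_fraction`
  (default 0.10) of the *inter-reserve* cells by area, ties at the
  quantile boundary included. Reserve-interior cells carry NLCC 0
  trivially and are excluded from the slice by default — with ~5%
  reserves on each side they would otherwise consume the whole 10%
  slice and the "corridor" would just be the reserves. Slicing by area
  keeps per-species corridor extents comparable, which the overlap
  statistic requires; cost-ratio slicing (`NLCC ≤ f·LCP`) is available
  via `method="cost_ratio"`.
- **Circuit**: edge conductance = 1/cost; the graph-Laplacian system
  is solved sparsely (spsolve on the interior block) with the source
  supernode at voltage 1 and the ground at 0. Effective resistance =
  1 / total source current. The per-cell current map (half the summed
  absolute incident edge currents, mapped back through the
  pre-contraction cell pairs) is reported normalized to unit net
  source-to-ground flow, so it is invariant to uniformly rescaling the
  resistance surface — rescaling by k scales LCP, NLCC and effective
  resistance by exactly k and leaves the current pattern unchanged.
  Disconnected terminal pairs yield an explicit infinite-resistance
  result rather than an error.

Tolerance policy: transforms, stacking and graph construction are
exact; solver stages are reproducible to ≤1e-8 (the Kirchhoff residual
of the sparse solve is ~1e-15 in practice).

## Comparison layer

Pearson correlations are computed on continuous products
(suitability, current, NLCC) over jointly valid finite cells; percent
overlap only on binary corridor masks, as symmetric Jaccard
(100·|A∩B|/|A∪B|) by default. With equal-area slices |A| ≈ |B|, so
Jaccard and the averaged asymmetric convention (available as
`mean_asymmetric`) nearly coincide. The proxy ranking scores every
model (including the stacked one) by its mean pairwise value against
the single-species models only; exact ties break alphabetically and
are flagged.

## Synthetic landscapes

The generator emulates the statistical structure of a transect-based
savanna corridor study: a ~1-km equal-area grid over a study area of a
few hundred to a couple of thousand km²; smooth autocorrelated fields
(Gaussian-filtered white noise, kernel sd 5 cells) standing in for
vegetation indices and land-cover fractions; exact Euclidean
distance-to-feature fields standing in for distance to settlements,
rivers or reserves (all layers standardized over valid cells); two
disjoint reserves (~5% of cells each) in opposite corners; and species
whose occurrence probability is a known logistic function of the
predictors, detected along north–south transects in every
`spacing/cell_size`-th column as independent Bernoulli trials with
probability `detection_scale × truth`. The assemblage generator draws
independent specialist coefficient vectors (sd 1.5 on the log-odds
scale) and adds a niche-centroid generalist whose coefficients are the
specialists' mean; intercepts are calibrated so mean suitability sits
near a target prevalence (default 0.25).

What it deliberately does not emulate: perpendicular-distance
detection functions (detection is single-visit Bernoulli), temporal
replication or seasonality, observer effects, spatially biased survey
effort, land-cover class structure, or any real geography. Passing
tests therefore demonstrate that the *pipeline* recovers known
structure under idealized sampling — not that any given field dataset
meets these assumptions.

The planted-corridor fixture plants an L-shaped high-suitability
channel (contrast ×10) between the default corner reserves. For
corridor-recovery checks the landscape is sized 100×100 with a
width-3 channel so the channel occupies ~6% of cells — necessarily
below the 10% slice, which otherwise could not contain it.

## Study sizes used by the test suite

The end-to-end assemblage experiments run at a reduced scale chosen
once as this package's synthetic study conditions: 40×40 one-km cells,
seven species (six specialists + the generalist), transects in every
column, detection scale 0.5, two fast learner families (logistic and
the maxent-like model), three holdout repetitions, and retention
threshold 0.5 (synthetic effects are weaker than the field data the
0.90 default reflects). Twenty seeded replicates of this experiment
back the proxy-species properties.

## Replication behaviour of the proxy ordering

Across the twenty seeded assemblage runs the generalist is the
top-ranked single-species proxy in every run, under both resistance
scalings and so the choice of scaling never changes *which* species
predicts the others best. The *complete* species-by-species ordering,
however, is not always identical between scalings: species whose mean
pairwise correlations differ by less than ~0.005 can swap adjacent
ranks (per-run Spearman ρ between the two scalings' score vectors
ranges 0.82–1.00). Exact full-ordering identity is a knife-edge
property of near-tied means and should not be expected to replicate,
while the identity of the best proxy is robust.

## Known limitations

- Habitat suitability is used as a proxy for movement resistance; the
  two are not the same thing, and no movement or genetic data enters
  the model.
- Pairwise connectivity only (one source, one ground); multi-node
  corridor networks are out of scope.
- No significance testing or spatial-autocorrelation correction in the
  comparison layer.
- Inputs must arrive aligned on one lattice; there is no reprojection.
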