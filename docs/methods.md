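# Methods

This note documents the statistical procedures implemented in `marsflora`,
the conventions and defaults behind them, what the synthetic-data generator
does and does not emulate, and the design choices made where the method
family leaves them open.

## Survey summaries

Surveys are presence-only: one row per occurrence of a single species, with
optional endangered/endemic flags. Three pre-modelling summaries are
provided per species: record counts (for the minimum-record bar), pairwise
point distances, and the pseudoreplication report.

* **Distances** default to haversine on WGS84 (radius 6371.0088 km), via
  `sklearn.metrics.pairwise.haversine_distances`; a planar option (meters →
  km) is available for projected inputs and warns when applied to geographic
  coordinates. Study-wide figures are the across-species averages of the
  per-species minimum and mean, taken over species with ≥2 records only
  (pairwise distance is undefined otherwise).
* **Pseudoreplication**: a species' point pair closer than one climate-grid
  cell samples the same predictor values twice. The report buckets points
  into the half-open lattice `[k·c, (k+1)·c)` anchored at 0° with
  `c = 1/120°` (30 arc-seconds, the global bioclimatic lattice) and counts
  cells holding ≥2 points per species. Boundary points belong to the
  higher-index cell; the report is invariant to translating all points by
  integer multiples of `c`.

## Rasters and predictor preparation

One fixed grid convention is used everywhere: row-major from the upper-left
corner, square cells, values at cell centers, cell `(r, c)` covering the
half-open square closed on its top and left edges. Nodata is NaN internally;
files are ESRI ASCII grids (plain text) with a numeric sentinel.

* **Bilinear resampling** interpolates the four surrounding source cell
  centers (scipy `RegularGridInterpolator`); any NaN neighbor makes the
  output cell NaN; target centers outside the source center lattice clamp to
  the nearest valid row/column. Resampling a raster onto its own grid
  reproduces it exactly.
* **Terrain**: slope and aspect from Horn's 3×3 weighted differences;
  aspect is the *downslope* azimuth, degrees clockwise from geographic
  north, in [0, 360), with perfectly flat neighborhoods assigned 0.
  Curvature is the discrete Laplacian. Northness defaults to **sin(aspect)**
  — kept deliberately, as some studies use the sine transform — with
  cos(aspect) available via `northness="cos"`. On geographic grids the
  gradients are scaled by meters-per-degree with a per-row latitude
  correction. Border cells are nodata.
* **Aggregation** to a coarser prediction grid is the nodata-aware block
  mean over `factor × factor` windows; with no nodata and dividing
  dimensions it preserves the global mean exactly. A factor-10 aggregation
  of ~30 m cells gives the ~0.1 km² prediction cells used for stacking.
* **PCA screening** reduces a correlated predictor set to `keep` variables:
  layers are standardized over jointly valid cells, the correlation matrix
  eigendecomposed, components visited by decreasing variance, and from each
  the unselected variable with the largest absolute loading is taken unless
  it correlates above `r_max = 0.85` with an already-selected one; visits
  cycle until `keep` names are found. This greedy protocol is one of several
  defensible readings of "select the least correlated predictors"; a known
  predictor list can always be supplied directly to bypass screening.

## The multi-response MARS model

**Response matrix.** Species with fewer than `min_records = 2` points are
dropped (with their points); the remaining points form the rows, species the
columns, and each row contains exactly one 1. A point is thus a presence for
its own species and an *inventory pseudo-absence* for every other modelled
species. At least two species are required — with one, the multi-response
construction is meaningless.

**Forward pass.** Reflected hinge pairs `max(0, x−k)`, `max(0, k−x)` are
added greedily, scoring every (parent, variable, knot) candidate by the
total least-squares RSS over all response columns (computed incrementally by
orthogonalizing the candidate pair against the current basis). Ties break by
smallest RSS, then lowest variable index, then smallest knot — fully
deterministic. Candidate knots per variable are the unique observed values,
minus those with fewer than `min_span = 3` observations strictly on either
side (the standard guard against edge hinges), thinned to at most 50
quantile-spaced values. Defaults: `max_terms = min(21, 2·n_predictors + 1)`
basis functions including the intercept; relative-improvement stop at
`tol = 1e-4`; interaction degree 1 (additive). Degree-2 products are
implemented (parents = existing terms not already using the variable) but
off by default: the analyses this package supports showed only
single-variable effects, and additive bases keep the per-species refit
well-conditioned at small n.

**Backward pass.** Standard deletion pruning: repeatedly remove the term
whose deletion least increases the pooled RSS, score every model on the path
with `GCV(M) = (RSS/nS) / (1 − C(M)/n)²`, `C(M) = M + 2·(M−1)/2` (M = basis
size including intercept, S = responses), and keep the path minimum. The
intercept is never deleted. Note that pooled 0/1 responses make per-term RSS
gains small relative to the Bernoulli noise floor, so pruning is aggressive:
final bases of roughly 2–8 shared terms for communities of 10–200 species
are the *expected* behavior of this estimator, not a defect. Species
differentiate through their coefficients, not through private basis terms.

**Per-species refit.** Each species' column is refitted by a binomial GLM
(logistic link) over the shared basis using IRLS, with fitted probabilities
clipped to `[1e-6, 1−1e-6]` inside the iteration; convergence at max
coefficient change `< 1e-8` or 25 iterations. Separated or one-class
responses converge to the clip boundary and are returned with a
`boundary` flag rather than raising — a species whose two points are
environmental outliers still gets a (flagged) model.

**Diagnostics.** Per species: binomial deviance of the fit and of the
intercept-only null, and `pseudo R² = 1 − residual/null` (can be negative
for boundary fits; ≤ 1 always). Per predictor: the *drop deviance* — remove
the variable's terms, refit every species' GLM, average the deviance
increase across species (clamped at 0 within refit tolerance) — and the
resulting rank; predictors absent from the final basis score 0.00 by
construction.

**Prediction** evaluates the inverse-logit of each species' linear predictor
over the basis on a raster stack, clamps to [0, 1], and propagates nodata
from any layer the basis uses. Because the response columns encode *which
species was recorded where* rather than absolute occupancy, the surfaces are
relative suitabilities compressed toward the species' share of the survey;
all thresholding below is data-driven partly for this reason.

## Range thresholds

Per species, the modelled probabilities at its own presence points give the
mean, median and sample standard deviation (`ddof = 1`; small samples
dominate this data and the population/sample choice is documented and
switchable). Rules:

* mean / median / max-SSS: presence where `p ≥ t` (≥, not >, so a species'
  own defining points stay inside degenerate ranges);
* SD band: presence where `mean − sd ≤ p ≤ mean + sd`, a literal two-sided
  band that includes cells *below* the mean and excludes cells far above it;
  `sd_band_one_sided` converts it to `p ≥ mean − sd` for users who consider
  the upper exclusion an artifact of the band's wording.

The max-SSS threshold maximizes sensitivity + specificity with the other
modelled species' points as pseudo-absences; candidates are the distinct
observed probabilities (the optimum of a step function lies at an observed
value), ties take the smallest threshold. Species need ≥2 valid presence
probabilities to be thresholded at all.

## Validation

The primary score is the **inclusion proportion**: the fraction of an
independent survey's points for the species that fall in presence cells
(points on nodata cells leave the denominator, with a logged count).
Group means weight species equally; point-weighted means are also emitted.
Species absent from the model are skipped and listed. The **minimum-record
sweep** recomputes the per-method mean over species subsets with ≥3/≥5/≥7/≥10
training records — the data-volume question. Sensitivity/specificity against
inventory pseudo-absences is reported but deliberately de-emphasized: the
pseudo-absence pool is nearly identical for all species, so specificity
measures modelled range size, not true negatives (wider rules score lower
mechanically).

## Stacked biodiversity surfaces

Richness is the cellwise count of presences over (a group of) species;
rarity the cellwise sum of `1/range_cells`, so each non-empty-ranged species
contributes exactly 1 to the map total — an identity checked to 1e-9 in the
tests. Range size is measured in prediction-grid cells; a constant cell area
cancels in all relative comparisons. Correlations between maps are Pearson
over the jointly valid domain *including zeros* (the domain choice is
otherwise unstated in this method family; a land mask can restrict it).
Quintile classes rank the non-zero cells ascending with stable (cell-order)
tie-breaks and cut into five as-equal-as-possible blocks; mask overlap
reports the share of mask cells in the top classes, counting class-0 cells
in the denominator.

## Synthetic data

`make_landscape` builds standardized smooth predictor surfaces: Gaussian-
filtered noise (smoothing length 1/16 of the short grid side) mixing a
shared latent field (weight √ρ) with an independent field, plus a mild
linear gradient in a random direction (weight 0.2), and a DEM-like layer.
At ρ = 0 the mean absolute pairwise layer correlation stays below 0.15; the
residual correlation comes from the finite number of independent smoothing
patches.

Virtual species live in the same hinge-logistic family the model fits —
deliberate, so recovery failures indicate implementation bugs rather than
misspecification. `random_species_specs` draws one or two single-knot
effects per species at interior landscape quantiles, slope magnitudes around
4 (standardized predictor units), and calibrates each intercept by bisection
to a landscape prevalence drawn from 0.10–0.35. Training sample sizes are
log-uniform on 2–69, matching the spread of records per species in national
floristic inventories (most species rare, a few abundant); independent
surveys are drawn from the same truth with a disjoint seed stream. Presence
points are sampled with probability proportional to the true surface and
placed uniformly within their cell. The "true range" used for overlap
scoring is `p ≥ 0.5` — arbitrary but fixed.

What the generator does **not** emulate: spatial sampling bias (roadside or
elevation effects — real surveys over-sample mountains), detection error,
taxonomic noise, non-hinge (e.g. Gaussian-bump) responses, and spatial
autocorrelation of residuals. Passing recovery tests therefore demonstrates
correctness of the estimator and pipeline under the model's own assumptions,
not robustness to the full messiness of field data.

## Standing experiments

* **Parameter recovery** (`experiments.knot_recovery`): 20 species on a
  200×200 landscape, 50 training points each, responding to *shared*
  per-predictor thresholds with sharp (slope 14) responses and prevalence
  0.25–0.45. Shared thresholds are the regime the multi-response model
  assumes — a pooled basis can only represent community-level knots, and
  pooled fits over many species retaining only a handful of shared knots is
  the observed shape of this estimator. Knot identification is scored on the noiseless
  piecewise-linear responses (the forward pass's regression contract; on
  binary indicators the least-squares knot for a sigmoid truth is biased —
  an estimator property, not a bug), requiring every true knot within one
  candidate-grid step. Range recovery runs the full presence-only pipeline
  and requires mean Jaccard ≥ 0.5 between SD-band maps and true ranges.
* **Minimum-record sweep** (`experiments.inclusion_sweep_trend`): 10
  replicate default communities (100×100, 20 species, log-uniform record
  counts); the seed-averaged inclusion must be non-decreasing along the
  ≥3/≥5/≥7/≥10 cutoffs for every method, with 0.03 of Monte-Carlo wobble
  tolerated (≈1 SE of the subset means at these sizes). The same replicates
  check the method ordering: with wide high-probability plateaus, SD-band
  and max-SSS admit more independent points than mean/median.

Problem sizes throughout (grids of 100–200 cells a side, communities of
8–30 species, ≤10 replicates) are chosen so the full suite and the
reproduction script each run in well under a minute on one core while
leaving clear statistical margins.

## Known limitations

* The basis search optimizes least squares on 0/1 indicators, not the
  binomial likelihood; only the per-species refit is binomial. This mirrors
  the established multi-response MARS adaptation, and is why predicted
  surfaces are relative rather than calibrated absolute probabilities.
* GCV pruning at penalty 2 is aggressive on pooled indicator responses;
  communities with genuinely species-specific thresholds will be summarized
  by compromise knots.
* No reprojection: all rasters and surveys must share a CRS. No GeoTIFF IO;
  grids are exchanged as ESRI ASCII text.
* Specificity against inventory pseudo-absences should not be used for
  model selection (see Validation above); it is reported for completeness.
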