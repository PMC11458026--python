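# Methods

This note records the models, defaults and judgement calls behind
`plankgrid`, in the spirit of a package vignette: what is assumed, what is
tunable, and what passing the test suite does and does not demonstrate.

## Spatial model and working coordinates

All geostatistics run in planar km via an equirectangular projection
anchored at the study-polygon centroid, with fixed constants
111.320 km/° longitude (scaled by cos of the anchor latitude) and
110.574 km/° latitude. At the few-hundred-km scale of a shelf survey the
distortion is negligible, and fixed constants make distances exactly
testable. Cell sizes selected in km are converted to degrees of latitude
(`km_to_degrees`, rounded to 2 decimals) for grid construction.

Semivariograms use the standard decomposition γ(h) = c₀ + γ_struct(h) for
h > 0 with γ(0) = 0. Two families are provided: spherical, and an
exponential in the *practical-range* parameterization
γ_struct(h) = c₁(1 − e^{−3h/a}) so that a marks ~95 % of the sill in both
families. The estimator is the classical method of moments on equal-width
lag bins (default 15 bins to half the maximum pairwise distance, a common
variography heuristic); fitting minimizes Cressie-weighted least squares
Σ N_b(γ̂_b − γ_b)²/γ_b² with box constraints and five seeded starting
points. An optional polynomial trend (order 0/1/2, or AIC-selected) is
removed by OLS before variography; the simulated reference fields are
stationary, so order 0 is the default.

## Information content and the optimal cell size

The cell-size criterion trades removal of nugget variance against
retention of structured variance:

- n̄(v) = max(1, ρ·v²) with ρ the dataset's global station density: the
  expected number of stations averaged in a v×v cell (per-cell counts vary
  in real surveys; the global density is the only well-defined summary).
- PN(v) = 1 − 1/n̄(v): averaging n iid nugget contributions divides their
  variance by n, so PN is the removed fraction.
- PS(v) = 1 − γ̄_struct(v)/c₁ with γ̄_struct the structured semivariance
  averaged over distinct pairs of an m×m lattice spanning the cell
  (default m = 10, a numerical regularization integral): the fraction of
  spatially structured variance that survives block-averaging.
- f(v) = PN·PS, maximized over the search grid (default 10–200 km, step
  0.5 km; ties to the smallest v).

The product form is this package's explicit formalization of the
minimize-nugget / keep-signal trade-off; it yields an interior optimum and
the expected monotonicities (PN non-decreasing, PS non-increasing in v),
both asserted by tests. It is deliberately isolated behind
`information_curve` so an alternative score is a one-line swap. The
consensus across taxa is the median of per-taxon optima; the reported
`max_relative_f_loss` quantifies the worst sacrifice the compromise imposes
on any single taxon.

## Bootstrap aggregation

Cell means are means over B = 10 000 bootstrap replicates of the resample
mean (resample size n, with replacement), applied per (cell, taxon,
transform) on raw and log(x+1) values. The estimator's expectation is the
plain sample mean and its Monte-Carlo error shrinks as s/√(nB); the
bootstrap's role is robustness of the *pair* of raw/log summaries under
very unequal station counts. Natural log is used for log(x+1) (the base is
a monotone rescaling per taxon and does not affect the clustering
geometry). Resampling streams are counter-based, keyed by (seed, cell row,
cell column, taxon index, transform), so results are independent of
processing order and reproducible bit-for-bit. Resamples are drawn per
taxon rather than jointly across taxa — cross-taxon correlations within a
cell are not needed by any downstream consumer of the cell means.

Cells are half-open [x, x+s) × [y, y+s), making station assignment a total
function (boundary stations go to the greater-side cell). A cell enters
the analysis only when *every* dataset meets its station minimum there
(default 1); exclusions are reported, not silently dropped.

## Clustering

Clustering input is the Hellinger transform of the *log-mean* matrix
restricted to dominant taxa (> 0.5 % relative abundance) minus the
aggregate exclusion list; aggregates would double-count their members in
the distance geometry but remain meaningful as indicators. FANNY is
implemented in dissimilarity space (Kaufman–Rousseeuw objective), not as
centroid fuzzy k-means, so it accepts the Hellinger distance matrix
directly. Memberships are updated by the classical fixed-point rule
u_iv ∝ a_iv^{−1/(r−1)}; because that rule is not guaranteed monotone, each
sweep's objective is checked and the iteration stops (keeping the previous
memberships) if a sweep would increase it — the recorded objective is
therefore non-increasing by construction. Five restarts from symmetric
Dirichlet(1) memberships are run and the best objective kept; restart
streams are keyed by cell id, which makes results equivariant under row
permutation. The default membership exponent is r = 1.2 (close to crisp;
values near 1 suit community matrices where overlapping but distinct
assemblages are expected).

k is never auto-selected. The diagnostics table reports, per candidate k:
mean silhouette width and Mantel correlation (Pearson r between the
distance matrix and the 0/1 crisp-partition model matrix) on the
max-membership labels, and a Kelly–Gardner–Sutcliffe-style penalty
(rescaled average within-cluster spread + k) computed on an average-linkage
tree — a surrogate for the original hierarchical formulation, flagged as
one diagnostic among three.

## Indicator analysis

IndVal uses raw-scale cell means: indicator status should reflect actual
abundance concentration, not variance-stabilized values. A_tc normalizes a
taxon's per-cluster mean abundances to sum to one; B_tc is occupancy;
IV = A·B is reported on the 0–1 scale with threshold 0.25. Significance:
cell-level label permutations (the grid cell is the analysis unit),
n_perm = 999 by default, add-one p-values, Benjamini–Hochberg step-up at
α = 0.05 across taxa. All taxa (dominant, secondary, excluded aggregates)
are tested.

## Drivers and inter-annual machinery

The abiotic PCA takes log(x+1) of temperature, salinity, depth, NOx
(= NO₃⁻+NO₂⁻), NH₄⁺, PO₄³⁻, Si(OH)₄, POM and chlorophyll a, centered and
scaled (a correlation-matrix PCA); depth is logged like the rest for
uniformity. The biotic PCA takes Hellinger-transformed cell means of the 7
phyto-microplankton groups, centered but not scaled (the transform already
equalizes scales). Signs follow a deterministic rule (the largest-|loading|
variable of each dimension is positive). The N/P ratio enters as a
supplementary variable whose coordinate on a dimension is its Pearson
correlation with the dimension's scores. Mixed-model fitting itself is out
of scope: the design export provides Dim.1/2 abiotic, Dim.1 biotic, their
products, cluster labels and per-taxon raw means, plus the cross-PCA
correlation matrix that should be checked before fitting.

The inter-annual comparison re-runs grid + clustering inside a restricted
polygon (the overlap of two surveys; k = 2 by default), computes
per-cluster means and per-cell differences (year B − year A) on raw cell
means, and anomaly series as deviations from the multi-year mean with a
standardized (sample-sd) companion — the anomaly definition is the
package's own, as none is canonical.

## The synthetic reference scenario

`scenario_default()` emulates a winter shelf survey: a southern-North-Sea-
like polygon (~600 × 650 km), K = 5 contiguous regions (Voronoi cells of
k-means centers of a uniform sample — well-spread, deterministic), and a
shared spherical variogram c₀ = 0.3, c₁ = 1.0, a = 60 km on the log scale.
Twenty taxa: 12 mesozooplankton profiles with region preferences spanning
four orders of magnitude in abundance (the two rarest, Chaetognatha and
Evadne, fall below the 0.5 % dominance cut by design), 5 planted indicator
taxa — one per region, hard-zero outside it, abundant enough to be
dominant — distributed over the three gears, and 3 aggregates (Copepoda,
Calanoida, Crustacea nauplius) that are exact sums of their members.
Sampling effort: 140 + 130 scattered stations and 860 along-track pump
samples, matching the heterogeneous-coverage situation the pipeline
addresses. Environmental variables are log-normal with region-linked means
riding on a shared random field; 7 phyto groups each prefer one region.

What the generator does *not* emulate: temporal dynamics within a survey,
larval drift, taxonomic misclassification, gear selectivity and anisotropic
spatial structure. Recovery results on synthetic data therefore demonstrate
the pipeline's internal correctness and statistical calibration, not
field-data performance; on real surveys the latent structure is unknown and
k remains a judgement call.

## Problem sizes and numerical choices

Tests and the acceptance script run the reference scenario as-is
(1130 stations, ~40–60 kept cells, B = 10 000, n_perm = 999) and use
n = 300–500 points with 10–30 replicates for field-simulation studies —
sizes chosen so the full suite completes in about a minute while keeping
Monte-Carlo error well inside the asserted tolerances. Gaussian fields are
drawn by dense Cholesky factorization (≤ 2000 points) with a small jitter
retry for numerically semidefinite covariances. Variogram fits guard the
Cressie weights with a 1e-12 floor; FANNY treats non-positive marginal
costs by committing the cell fully to the best cluster (the objective's
boundary optimum); zero-sum rows under the Hellinger transform map to zero
rows and are flagged rather than dropped.

## Known limitations

- Isotropic variograms only; no kriging of empty cells (they are excluded).
- The expected-stations-per-cell term uses the global station density, so
  strongly clustered designs (e.g. pure transects) make PN optimistic at
  small v; the along-track dataset in the reference scenario is dense
  enough that this does not move the consensus materially.
- The KGS diagnostic is a tree-based surrogate; its absolute values are not
  comparable across datasets, only its argmin matters.
- Permutation p-values have resolution 1/(n_perm+1); with BH at 0.05 and
  n_perm = 999 the operating point is well resolved, but very small
  cluster counts can make the minimum attainable p too coarse.
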