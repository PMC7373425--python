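# Methods

## Problem and model

Mammary acini grown in 3D culture are hollow, single-cell-layered spheres
of epithelial cells around a lumen. When an oncogenic program is switched
on in a sparse, random subset of cells (the *transduced* cells), some acini
develop locally multilayered, fast-proliferating outgrowths ("tumor
outcome") while others do not. The central question this package addresses
is which start-of-imaging spatial features of transduced-cell groups
predict that outcome — in particular whether spatial proximity of several
transduced cells matters more than any whole-acinus property.

The unit of analysis is the **cluster**: a group of transduced cells in one
acinus that are closer to each other than to the other transduced cells of
that acinus. Clusters are found per acinus by

1. pairwise Euclidean distances between transduced-cell centroids (µm),
2. agglomerative hierarchical clustering with complete linkage, and
3. an adaptive (dynamic) cut of the dendrogram branches; transduced cells
   detached by the cut become singleton clusters, so the result is always a
   partition.

For every cluster nine features are computed (counts, densities, pairwise
distances, contact counts; see the `feature_extraction` module docstring
for the exact definitions), and a binary tumor outcome is attached. Tumor
prediction is analysed by **exhaustive logistic model selection**: all
2^9 = 512 feature subsets are fitted by maximum likelihood and ranked by
the small-sample-corrected Akaike information criterion

    AICc = -2 logL + 2k + 2k(k+1)/(n - k - 1),

with k counting the intercept and n the number of clusters. Models are
compared via AICc differences Δi and Akaike weights
wi = exp(-Δi/2) / Σj exp(-Δj/2); the confidence set keeps Δ ≤ 3. Variable
importance is the sum of Akaike weights of the models containing a
feature. A logistic model with a per-acinus random intercept (Laplace
approximation) controls for acinus of origin.

## Clustering: adaptive tree cut

The published family of dynamic tree cut algorithms adapts the cut height
to the shape of each branch instead of slicing the dendrogram at one
height. This package implements a dendrogram-only top-down variant:

- Starting at the root, a merge at height *h* is **split** when at least
  one of its sub-branches is markedly more cohesive than the join:
  *h* > `gap_ratio` × (internal height of the tighter multi-leaf child),
  default `gap_ratio = 2`.
- Merges below `height_floor_frac` (default 0.3) × root height are never
  split. This anchors the decision to the acinus scale: locally uneven but
  low-lying branches — the cells of one spatial group — stay together.
- Branches smaller than `min_cluster_size` (default 2) are not clusters;
  their leaves are promoted to singleton clusters, which realises the
  convention that an isolated transduced cell is its own cluster.
- An optional `max_merge_height` ceiling (µm) forces splits above an
  absolute height; it is off by default.

Consequences fixed by contract: one transduced cell yields one singleton;
two transduced cells always form one 2-cell cluster (a single-merge tree is
one branch); duplicate coordinates merge first. Complete linkage is
implemented directly so that equal merge heights break deterministically
(lexicographically smallest (min leaf id, max leaf id) pair first); scipy's
implementation is used as an independent oracle in the tests, not as the
implementation.

The exact variant and parameters used in the original cohort analysis are
not published; results on real data may be sensitive to this choice, which
is why all cut parameters are exposed in the run configuration.

## Feature conventions

- The acinus is treated as a sphere with diameter Dmax = the distance
  between its two most distant cells; cell density = n / (π·Dmax²)
  (cells/µm² of sphere surface). Acini with fewer than two cells, or all
  cells coincident, are excluded with a log entry.
- The cluster sphere ("cluster volume") is centred at the unweighted
  centroid of the member cells with diameter = distance between the two
  farthest members. Ball membership is closed (≤). Because the sphere is
  centred at the centroid, members of a spread-out cluster can fall outside
  their own volume (an equilateral triangle with side D has vertices at
  D/√3 > D/2); the cells-in-volume count honestly reports what the sphere
  contains.
- Contacts are strict: two cells are in contact when their centres are
  *less than* (mean cell diameter + 2 SD) apart. The diameter statistics
  are taken per acinus from the cell diameter column when present,
  otherwise from configuration defaults (mean 10 µm, SD 1 µm — defaults,
  not measured constants).
- Singleton conventions: cells-in-volume = 1 (plus exactly coincident
  cells), mean pairwise distances = 0, contacts = 0.
- The transduced fraction in the volume is (transduced cells inside the
  sphere) / (all cells inside the sphere).

## Outcome attachment

With explicit annotations, outcomes are copied per (acinus, cluster). With
a lineage table, a cluster is tumor-associated when any member's lineage
expanded at least `fold_expansion_threshold`-fold (default 4) over the
observation window. The fold threshold is a configurable heuristic for the
phenotypic call (multilayering, increased proliferation), not a measured
rule, and is surfaced in the configuration for that reason.

## Model selection and inference

- Logistic fits use Newton/IRLS to gradient norm < 1e-8 (max 100
  iterations) with step halving. Quasi-complete separation is flagged when
  any coefficient exceeds 15 on standardised predictors; separated fits
  are retained (their AICc is defined) but marked, because their MLEs are
  divergent by construction.
- Subsets that are rank-deficient or violate n − k − 1 > 0 are flagged
  infeasible and excluded from the weight normalisation but listed in the
  output.
- Features enter untransformed, so exponentiated coefficients are odds
  ratios per unit (per additional transduced cell, per µm, ...).
- Confidence intervals are Wald (coef ± 1.96·SE, exponentiated). Profile
  likelihood intervals would differ slightly; Wald was chosen for
  determinism and speed.
- Variable importance: the sum of Akaike weights over models containing
  the feature, the standard bounded measure for this procedure. A literal
  sum of AICc values per feature is also emitted as a diagnostic column
  (`aicc_sum`), but it is unbounded and not comparable across runs.
- The mixed model takes the three most important features as fixed
  effects, adds the starting number of normal cells in the acinus as a
  main effect plus its interactions with each fixed effect, and a
  per-acinus random intercept. The marginal likelihood is maximised under
  the Laplace approximation (one quadrature point), the same approximation
  lme4's `glmer` uses at nAGQ = 1; the test suite pins the implementation
  to `glmer` reference values frozen from an identical dataset. Whether
  the normal-cell count should enter as a main effect is ambiguous in the
  source description; it is included here (interactions without main
  effects are rarely defensible), and the design columns are reported so
  the choice is visible.

## Synthetic-acinus generator

The generator emulates the statistical structure the analysis assumes and
provides ground truth for end-to-end validation:

- **Geometry**: cell centroids on a sphere shell (radius 18–28 µm, radial
  jitter 1.5 µm) with a minimum centre separation of 8 µm via dart
  throwing; after repeated failures the separation relaxes by 5% with a
  logged warning (bounded; then generation fails). A monolayer shell, not
  a filled ball, matches polarised single-layer epithelia and makes the
  maximal span ≈ 2 × radius, as the acinus-sphere density feature assumes.
- **Scale**: 20 acini of 20–50 cells with 5–10 transduced cells each
  (≈150 transduced cells per 20-acinus cohort, i.e. mean 7.5 per acinus —
  a modelling choice consistent with the cohort totals, since per-acinus
  counts are not published).
- **Aggregation**: per acinus, 2–4 seed cells are chosen uniformly; each
  remaining transduced label goes to the unlabeled cell nearest any seed
  with probability `aggregation` (default 0.9), else to a uniform random
  cell. `aggregation` = 0 is complete spatial randomness of labels; 1 is
  maximal co-location.
- **Outcomes**: cluster-level, P(tumor) = logistic(β0 + β1·m) with m the
  number of transduced cells in the cluster. β1 defaults to ln 9 (each
  additional transduced cell multiplies the tumor odds by 9); β0 defaults
  to −2·ln 9, which puts singletons at P = 0.1, pairs at 0.5 and triples
  at 0.9 and yields cohorts with both outcome classes well represented.
  Outcomes are generated at cluster level because the cluster is the unit
  of analysis.
- **Reproducibility**: per-acinus RNG streams are spawned from the cohort
  seed, so cohorts are bit-reproducible and each acinus is independent of
  how many acini follow it.

What the generator does *not* emulate: growth dynamics, cell division and
movement during imaging, segmentation/tracking errors, uneven cell sizes
along the shell, or acinus-level heterogeneity in outcome propensity
beyond what cluster sizes induce. Passing recovery tests therefore show
that the pipeline correctly inverts its own generative assumptions at
realistic scale and noise — not that those assumptions hold in any given
imaging data set.

## Validation design and problem sizes

- Closed-form oracles: saturated 2×2 logistic tables (OR = 81), the AICc
  arithmetic identity, weight normalisation, 512-model enumeration.
- Brute-force oracles: complete-linkage merge heights vs exhaustive
  inter-set maxima (200 random instances, n ≤ 8); ball membership, mean
  pairwise distances and contacts vs double-loop recomputation (200
  random clusters).
- Parameter recovery: 100 replicate cohorts of 40 acini (aggregation 0.9,
  β1 = ln 9). Reported: bias and RMSE of the focal coefficient (from the
  single-feature fit, the generating model), Wald CI coverage of ln 9,
  and how often the focal feature tops the importance ranking; the null
  condition (β1 = 0, β0 = 0) verifies the top rate falls to chance
  (~1/9). Replicates whose focal fit is quasi-separated have divergent
  MLEs; they are counted and bias/RMSE are additionally reported with
  them excluded. With a steep generating slope (odds ×9 per cell),
  quasi-separation is expected in a small percentage of cohorts of this
  size — a property of the data regime, not an estimation failure.
- The acceptance script runs one study-scale cohort (20 acini) plus
  50-replicate recovery studies per condition; the test suite uses 100
  replicates for the recovery criteria and smaller cohort counts (12–15)
  for slow distributional properties. All simulation sizes are package
  choices balancing statistical resolution against runtime.

## Numerical choices and degenerate inputs

- Ball membership uses a 1e-12 µm absolute slack so that members exactly
  on the sphere count as inside under floating point.
- IRLS uses a 1e-10 ridge on the Hessian solve near separation; the mixed
  model optimises log σ within [log 1e-4, log 50] and reports σ below
  2e-4 as 0. Fixed-effect SEs come from a central-difference Hessian of
  the Laplace marginal likelihood.
- The group-level Laplace term is computed as
  ℓ(b̂) − b̂²/(2σ²) − ½·log(1 + σ²·Σw), which recovers the ordinary
  logistic likelihood exactly as σ → 0.
- Acini with < 2 cells or zero maximal span are excluded from features
  with a log entry; acini with zero transduced cells contribute no
  clusters; empty outcome classes abort the analysis with an explicit
  error rather than producing degenerate fits.

## Known limitations

- The adaptive cut is one member of the dynamic-tree-cut family; on real
  data the published variant with different parameters may partition
  border-line acini differently, which propagates to cluster counts and
  feature values.
- Wald intervals and the Laplace approximation can each shift third
  decimals relative to profile likelihood / adaptive quadrature.
- Post-selection inference: coefficients read off the best AICc model are
  conditioned on selection; the recovery harness therefore estimates the
  focal coefficient from the fixed single-feature model and reports the
  best-model coefficient separately.
- The XLSX ingestion requires an explicit column map because the layout
  of per-acinus sheets is not standardised; sheets become acini by name.
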