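# Methods

This note documents the models and procedures implemented in `rebrain`,
the choices made where the design was genuinely open, and what the test
suite does and does not demonstrate.

## The profiling model

Each of the 15 panel components (U87, BRAF, EGFR, PDGFRA, TP53, MGMT,
CDK1–4, COX-1/2, VEGFR2, TERT, CYP2D6) is treated as an independent
computational bioassay: a regression problem mapping molecular descriptors
to a pChEMBL-style activity (−log₁₀ of a molar potency). The ensemble
captures model uncertainty the way bagging does:

1. Draw `n_models` (default **1000**) random subsamples: a fraction
   `subsample_fraction` (default **0.7**) of the training rows without
   replacement, crossed with a random descriptor subset of size
   `descriptor_subset_size` (default **min(d, 5)**).
2. Fit ordinary least squares with intercept on each subsample. OLS is the
   simplest family consistent with reporting a "regression coefficient"
   per model; rank-deficient or constant-response subsamples are skipped
   (logged, not fatal).
3. Retain models with training R² ≥ `retention_r2` (default **0.5**).
   Retention implements the idea that only adequately fitting models
   should vote; the threshold is a quality floor, not a statistical test.
   Zero retained models is an explicit error advising a lower threshold.

All draws flow from one integer seed per ensemble, so a build is
reproducible bit-for-bit.

### Signature statistics

For a query descriptor vector `x` with per-model predictions `ŷ_k(x)`:

| statistic | definition | notes |
|---|---|---|
| `R2avg` | mean training R² of retained models | in [0, 1] |
| `SARactivity` | `clip((mean_k ŷ_k − y_min) / (y_max − y_min), 0, 1)` | min–max normalization uses the component's own training-activity range; the natural anchor absent an external scale |
| `SARstd` | `std_k ŷ_k / (y_max − y_min)` | population SD; exactly 0 when all retained models agree |
| `inmacActivity` | `SARactivity × R2avg` | confidence-weighted activity; bounded in [0, 1], reduces to `SARactivity` for perfect models; the repurposing feature |
| `inmacResolution` | `1 / (|bias| + 1e-6)`, capped at `1e6` | `bias` = mean signed residual of the **ensemble-mean** prediction over all training rows |

The bias is deliberately computed on the whole training table rather than
per model: an OLS model's residuals sum to zero on its own training rows,
so a per-model mean residual is identically zero and carries no
information. The ensemble-mean residual over all rows is the smallest
change that makes the statistic meaningful; for noiseless data it is ~0
and the resolution saturates at its documented cap.

### Applicability domain

The domain is the per-descriptor bounding box of the training data,
optionally widened by `tolerance_fraction × range` per axis (default
**0.0**). Strict mode rejects out-of-domain queries with the offending
descriptors named; lenient mode computes the signature anyway and flags it
`in_domain=False`. A box is crude but transparent; it matches the linear
model family, which extrapolates badly outside the training hull.

### Descriptors

The engine is descriptor-agnostic behind a provider contract (a
deterministic SMILES → ℝᵈ mapping). The bundled provider computes eight
constitutional descriptors via RDKit: heavy-atom count, molecular weight,
ring count, aromatic-atom count, heteroatom count, rotatable bonds, H-bond
donors and acceptors. These are coarse by design — cheap, interpretable
and adequate for linear ensembles; anyone with a better descriptor set
plugs it in without touching the engine.

## Pairwise similarity

Profiles are compared on their masked `inmacActivity` vectors in canonical
component order.

- **Regression**: the candidate is regressed on the reference (reference
  on the x-axis). `r2` is the squared Pearson correlation; `weight` is
  the OLS slope — the only pairwise regression quantity besides R² that
  matches reporting both an "R²" and a "weight" for a drug pair. A
  constant profile on either side yields `(r2=0, weight=0,
  intercept=mean(y))`, chosen so flat profiles never appear functionally
  similar.
- **Distance**: plain Euclidean distance over the masked components.
  Squaring the per-component differences neutralizes their sign, so
  opposite deviations cannot cancel. Distances are computed on activity
  vectors, not on regression weights — the geometric object the network
  is built on.
- **Significance**: strict `r2 > 0.6`; 0.6 exactly is not significant.

## Repurposing networks and ranking

A query = reference drug + MW cut (default **500 Da, inclusive**) +
distance threshold (default unbounded: the threshold is an interactive
refinement, so no finite default is imposed) + component mask (default all
15) + `top_k` (default **9**). The candidate pool is the MW-filtered
catalog plus the reference itself (the reference is never filtered out of
its own query). `star` mode draws reference–candidate edges only;
`mutual` mode additionally links candidate pairs within the distance
threshold, for network-shaped exploration.

Ranking is by ascending masked distance — the network is distance-built,
so distance is the ranking key; R², weight and the significance flag are
carried per row for the final pair-assessment step. Ties break by
(distance, lowercase name, drug id) so output is deterministic. Knockout
removes components from the mask (all 15 removed is an error), knock-in
restores them; shrinking the mask can only shrink distances, so knockout
never removes nodes from a distance-thresholded network.

Exports: GraphML or JSON node-link with all node/edge attributes (raw
distances are stored; any inverse-length rendering is a visualization
concern).

## Validation harness

The harness quantifies how much class structure the profiles carry:

- **Protocol**: stratified 80/20 split, grid search (3-fold CV,
  AUC-scored) confined to the training fold, default 5 repetitions with
  the mean reported. Split ratios and repetition counts are protocol
  choices, stated here because results are protocol-dependent.
- **Threshold**: binary class calls at probability 0.5.
- **Metrics**: confusion-matrix metrics implemented from their printed
  formulas with 0/0 → 0 conventions; ROC by sweeping distinct score
  thresholds (tied scores move together) and trapezoid AUC, which is
  exactly the tie-corrected Mann–Whitney statistic — the suite checks
  this identity to 1e-10.
- **Multiclass**: one-vs-rest — each class is relabelled against the union
  of the rest and evaluated as its own binary problem, giving a
  families × classes AUC table. A per-class binary model is trained for
  each relabelling rather than reading score columns off one multiclass
  model, matching the one-vs-rest definition exactly.
- **Families**: logistic regression, decision tree, random forest, SVM and
  a small feed-forward network, supplied by scikit-learn behind a uniform
  pipeline (standardization + model). Default grids are small and
  explicit (C ∈ {0.01, 0.1, 1, 10}; depth ∈ {3, 5, 10, ∞}; forest size
  ∈ {100, 300}; kernel ∈ {linear, rbf}; hidden layer ∈ {8, 32}).

## Synthetic data

The generators make the pipeline testable end to end and define exactly
what the tests can claim:

- `make_sar_training_set`: standard-normal descriptors, linear response
  with Gaussian noise. Noiseless tables make every OLS statistic exact, so
  ensemble recovery can be asserted to 1e-8.
- `make_profile_cohort`: class archetypes rejection-sampled in [0, 1]¹⁵ at
  a prescribed pairwise separation (default 1.0), members jittered with
  Gaussian noise (default sd 0.05) and clipped; MW uniform in (100, 600)
  Da so the 500 Da filter exercises both branches. Defaults give a
  clearly separable two-class problem — the regime where a sound harness
  must saturate.
- `make_engineered_pair`: `y = a + weight·x + e` with `e` centered and
  exactly orthogonal to `x`, scaled so the recovered (R², slope) hit the
  requested values to 1e-6 with only 15 points. Engineered candidates may
  leave [0, 1] (clipping would destroy exactness) and are raw vectors,
  not storable profiles. Slope and R² are coupled at the boundary: slope
  0 forces R² = 0 and vice versa; infeasible requests raise.
- `make_mock_catalog`: uniform-random profiles at catalog scale (2,809
  drugs in the scale tests).

What passing tests do **not** show: that real drug catalogs are separable,
that real SAR training data are linear, or that constitutional descriptors
suffice for real potency prediction. The synthetic cohorts have no
chemical correlation structure, no class imbalance beyond what is
configured, and no measurement error model beyond i.i.d. Gaussian noise.

## Numerical choices

- Ensemble statistics use population (ddof=0) standard deviations.
- Training R² is clipped to [0, 1] before retention comparison.
- Profile CSV I/O writes `repr`-exact floats and reads with round-trip
  float parsing, so write∘load is the identity bit-for-bit.
- `inmacResolution` cap 10⁶ and ε = 10⁻⁶ bound the statistic away from
  infinity for unbiased ensembles.
- Degenerate regression inputs (zero variance) return the documented
  (0, 0, mean) convention instead of NaN.

## Problem sizes

The test suite and the acceptance script run at deliberately compact
sizes — ensembles of 30–1000 models on 10–200-row training tables, cohorts
of 84–400 profiles, one catalog-scale (2,809-drug) ranking pass, and
single-point grids for the per-family harness checks — sizes at which
every asserted property is already fully determined. The library defaults
(1,000 models, 5 repetitions, full grids) remain the recommended analysis
settings.

## Known limitations

- The five-statistic signature is only as good as its training tables; no
  curated bioassay data ship with the package.
- Linear base learners cannot represent activity cliffs; the ensemble
  averages over descriptor subsets but never leaves the linear family.
- The applicability-domain box ignores descriptor correlations; a query
  can sit inside every marginal range yet far from the training manifold.
- One-vs-rest AUCs on heavily imbalanced classes should be read together
  with per-class prevalence; the harness reports AUC only.
- Profile regression treats the 15 components as exchangeable coordinates;
  it encodes no pathway topology.
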