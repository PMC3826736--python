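# Methods

## The AD-PS score

The AD Pattern Similarity score of a subject is the conditional probability
P(class 1 | x) under a binary logistic regression regularized with the
elastic-net penalty and fitted directly on high-dimensional feature
matrices — one column per voxel of a masked, vectorized tissue map (grey
matter, white matter or CSF), or one column per cognitive test score. With
classes anchored at cognitively normal (0) and AD (1), the score is a
similarity of a subject's anatomical or cognitive pattern to the patterns
found in AD patients, on the probability scale.

The fitted objective is the mean negative Bernoulli log-likelihood plus
`lam * (alpha * L1 + (1 - alpha)/2 * L2)` over the coefficients, intercept
unpenalized. The L1 part yields sparse weight vectors (interpretable,
voxel-level support); the quadratic part yields the grouping effect, which
makes correlated voxels enter together instead of one arbitrary
representative being selected — essential for stable discriminative maps
over spatially clustered atrophy.

### Solver

An iteratively reweighted least-squares (IRLS) outer loop builds a working
weighted least-squares problem from the current probabilities; a
coordinate-descent kernel with soft-threshold updates solves it over an
active set, with full Karush–Kuhn–Tucker (KKT) screens over all coordinates
to admit violators. Numerical safeguards, all standard for this solver
family:

- predictors are centered/scaled internally (population SD); coefficients
  are mapped back to the original scale (`standardize=True` default);
- fitted probabilities within `1e-5` of 0/1 are snapped there and their
  working weights floored (bounds the working response under separation);
  once the snapped fixed point is reached but the true KKT residual is
  still above tolerance, the snap is tightened to `1e-8` and iteration
  continues, so convergence is always declared on the *true* objective's
  KKT conditions (default tolerance `1e-7` per coordinate);
- each IRLS step is halved toward the previous iterate until the true
  penalized objective does not increase (proximal-Newton line search);
- probabilities are clipped at `1e-10` inside log-likelihood evaluation,
  and predictions are clipped to the open interval (0, 1);
- warm-started λ-paths stop early when the fitted model explains > 99.9%
  of the null deviance or a bottom-of-path fit cannot stabilize (complete
  separation with a vanishing penalty); remaining path entries repeat the
  last stable solution. A non-convergent single fit raises a distinct
  error carrying partial diagnostics.

`lambda_max` — the smallest penalty with an all-zero solution — anchors
every λ grid: 20 log-spaced points down to `lambda_min_ratio * lambda_max`,
with the ratio following the solver family's convention (`1e-4` when
subjects outnumber variables, `0.01` in the p ≥ n regime, where the bottom
of the deeper path is an effectively unpenalized, non-identifiable fit).

### Regularization selection

Nested three-way-split cross-validation: an external K1-fold split holds
each fold out for testing; the retained folds are split into K2 internal
folds, and the grid point with the highest mean validation accuracy wins.
Exact ties break toward larger λ, then larger α — deterministic and
favoring the sparser model. The classifier is refitted on all K1−1 folds at
the selected pair (warm-started down the path) and evaluated only on the
held-out fold. Defaults follow the protocol the package implements:
K1 = K2 = 10, 100 repetitions with fresh stratified random partitions,
medians of the per-repetition fold-averaged accuracy/sensitivity/
specificity reported. Folds are class-stratified so small cohorts cannot
produce single-class validation folds. A variant that averages the
per-fold winning parameters instead of taking the argmax is available as
`selection_rule="average"`.

Imaging modalities fix α and search λ only; the fixed value defaults to
0.1. A larger L1 share (e.g. α = 0.5) prunes mutually correlated planted
voxels to a small arbitrary subset, which destabilizes the stability-ratio
maps without helping accuracy; 0.1 keeps the quadratic share dominant while
still zeroing noise voxels. Cognitive data (25 columns) searches the full
2-D grid with α ∈ {0.1, …, 1.0}. Both are configuration options.

### Scores, composites, hypercube

Anchor-class subjects are scored **out of fold**: per repetition, each
subject's probability comes from the external-fold model that held it out;
the final score is the median across repetitions (midpoint interpolation
for even counts). Intermediate (MCI) groups are scored by **full-anchor
models**: per repetition, a K2-fold grid search on the complete anchor set
selects the penalty, the model is refitted on every anchor subject, and the
holdout median across repetitions is taken. Provenance (`out_of_fold` /
`full_model`) is recorded per subject.

Per-modality scores define a point in the unit probability hypercube with
fixed coordinate order (GM, WM, CSF, cognitive). The anatomical composite
is the plain sum GM+WM+CSF (range 0–3); the cognitive-anatomical composite
adds the cognitive score (range 0–4); no renormalization. Risk zones at
threshold 0.5: `low` iff every coordinate is strictly below, `high` iff
strictly above, otherwise `indeterminate` (boundary coordinates are
indeterminate). Corner distances are Euclidean.

### Discriminative maps

One full-anchor-data fit per repetition (penalty re-selected per
repetition's partition) gives a repetitions × p weight ensemble on the
original feature scale. The map value per voxel is mean/SD across
repetitions (SD with the n−1 convention). Degenerate voxels: SD = 0 with
zero mean → ratio 0; SD = 0 with nonzero mean → signed sentinel ±1e6,
flagged in `sentinel_mask`. Maps are written into masked volume space in a
fixed scan order (fastest-varying first axis; round-trip with
vectorization is exact) with the mask's affine. Sign convention: with
atrophy coded as lower intensity and AD as class 1, atrophy-driven voxels
carry negative weights; the package records signs and leaves anatomical
interpretation to the caller.

### Downstream statistics

Two-sample Kolmogorov–Smirnov tests compare score distributions across
strata (clinical status; age dichotomized at 75 years; functional status
dichotomized at FAQ = 2). The statistic is the exact ECDF sup-difference;
the p-value uses the asymptotic Kolmogorov distribution with effective
size n1·n2/(n1+n2). No multiple-comparison adjustment is applied, matching
the protocol the tables mirror. Stratified tables report per-stratum
medians, sizes and pairwise p-values; strata requested but absent are
reported as missing rows rather than dropped.

Conversion analysis fits a univariate Cox proportional-hazards model per
metric, with the covariate standardized internally (sample SD, ddof = 1) so
the reported hazard ratio is per 1 SD of the score; 95% CI =
exp(coef ± 1.96·SE), z = coef/SE. The partial likelihood is maximized by
lifelines with Efron's treatment of tied event times — the generator draws
continuous (exponential) times, so ties do not arise and Efron coincides
with Breslow. Subjects censored before the follow-up horizon enter the
survival analysis only; group-comparison tables keep them in their
clinical group.

## The synthetic study conditions

The generator emulates the statistical structure the analyses assume, at
desk scale, with ground truth retained:

- **Geometry**: a 20×20×20 grid per tissue (8000 voxels, full mask,
  1.5 mm isotropic affine) against n = 160 subjects (40 per group CN,
  ncMCI, cMCI, AD), preserving the p ≫ n regime at minutes-scale runtime.
- **Latent severity**: each subject draws a severity around its group mean
  (0, 0.35, 0.65, 1.0; SD 0.30, truncated at 0). Severity drives every
  planted effect, so the clinical gradient propagates to all modalities.
  The severity overlap sets the Bayes-level CN-vs-AD separability near
  95%, placing nested-CV accuracy in the realistic 90s rather than at a
  saturated 100% (real GM classifiers report high-80s), and making
  adjacent groups (ncMCI vs cMCI) genuinely hard, as observed in practice.
- **Images**: baseline intensity 1.0 at every voxel minus
  `depth × severity` inside 2 planted blocks per tissue (GM 64+27 voxels
  at depths 0.25/0.20; WM 27+27 at 0.18/0.15; CSF 27+27 at 0.15/0.12),
  plus iid Gaussian noise (SD 0.05, ~5% of baseline — plausible for
  smoothed modulated maps). Atrophy = lower intensity, fixing the sign
  convention. The noise level keeps individual planted voxels informative
  enough that the planted support is identifiable at n = 80 anchors, which
  is what the map-recovery checks exercise.
- **Cognition**: 25 named scores (ADAS-Cog subscores, RAVLT trials,
  Logical Memory, MMSE); 10 memory-weighted scores shift by 2 SD per unit
  severity, the rest are pure noise.
- **Strata**: age ~ N(75, 5²) plus 5 years per unit severity; FAQ =
  max(0, round(12·severity + N(0, 1.5))) — so age/FAQ-stratified analyses
  have real signal to find.
- **Survival**: exponential conversion times with log-hazard linear in
  standardized severity (0.69 per SD, hazard ratio 2.0), baseline hazard
  0.0165/month (≈45% conversion within the 36-month horizon),
  administrative censoring at the horizon plus random exponential
  censoring calibrated by bisection to 23% pre-horizon censoring —
  mirroring the observed conversion/censoring mix in the cohort structure
  this emulates. Group labels are fixed by the spec while conversion is
  drawn from the hazard, so a cMCI-labelled subject can be censored in a
  given draw: the label encodes atrophy grade, the record encodes observed
  conversion.

Everything is a pure function of (spec, seed) via independent named seed
streams, so cohorts reproduce byte-for-byte and repetition r's results
never depend on how many repetitions were requested.

**What the generator does not emulate**: brain geometry and anatomy,
registration/segmentation error, spatial noise correlation beyond the
planted blocks, site effects, non-proportional hazards, and informative
censoring. Passing tests therefore demonstrate that the *procedures* are
correct and recover planted structure under the stated conditions — not
that any particular real-data accuracy would be attained.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the default cohort with
K1 = K2 = 5 and 10 repetitions per model family, and smaller grids/cohorts
for unit-level checks; the protocol defaults (10/10/100) remain the
package defaults. Medians over 10 repetitions estimate the same quantities
as over 100 with more sampling noise, which the property-style checks
(bands, monotonicity, recovery fractions) absorb.

## Known limitations

- Pure-lasso (α = 1) support sizes can fluctuate by a voxel or two near
  the saturated end of the path; support monotonicity in λ is a reliable
  property at the elastic-net mixes the pipeline operates at (α ≤ 0.5).
- Under complete separation with a vanishing penalty the logistic MLE does
  not exist; path fits truncate at the last stable solution rather than
  chasing a diverging optimum.
- The Cox module fits univariate models only (one metric at a time), with
  no covariate adjustment, time-dependent effects or competing risks.
- Composite metrics are plain sums; no learned or weighted fusion.
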