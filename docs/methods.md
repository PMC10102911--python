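# Methods

## The problem

Randomized trials of targeted therapies often benefit only a subgroup of
patients, and which patients benefit may have to be read off a large panel
of baseline covariates rather than a single known biomarker.  The
cross-validated risk scores (CVRS) design addresses this for one binary
endpoint; this package implements its two-endpoint extension (CVRS2),
where the trade-off between two outcomes — efficacy and toxicity, efficacy
and quality of life, cost and effectiveness — defines the subgroup of
interest.  The package provides the full design: subgroup discovery,
hypothesis testing with a split significance level, permutation inference,
and a simulation harness for operating characteristics.

## Bivariate odds-ratio model

For two binary outcomes `Y1`, `Y2`, treatment indicator `t` and one
baseline covariate `x`, the joint model consists of two marginal logistic
regressions

    logit p1 = mu1 + lambda1*t + alpha1*x + beta1*t*x
    logit p2 = mu2 + lambda2*t + alpha2*x + beta2*t*x

coupled by a constant odds ratio `psi` (the ratio of the odds of `Y1 = 1`
when `Y2 = 1` versus `Y2 = 0`), modelled intercept-only on the log scale.
`psi = 1` is exactly outcome independence, in which case the likelihood
factorizes into the two univariate logistic likelihoods.  Given the two
margins and `psi`, the four joint cell probabilities are the Plackett
solution of the quadratic implied by the odds-ratio identity; we evaluate
the root in the form `p11 = 2*psi*p1*p2 / (S + sqrt(S^2 -
4*psi*(psi-1)*p1*p2))` with `S = 1 + (p1+p2)*(psi-1)`, which is
cancellation-free and continuous through `psi = 1`.

Covariate-dependent modelling of `log psi` is deliberately out of scope:
it buys little for risk scoring and is known to cause numerical trouble.

### Fitting

Two routes maximize the same exact likelihood:

* `fit_bivariate_model` (single covariate): L-BFGS-B with an analytic
  gradient, `log psi` box-bounded to ±10.  This is the reference path and
  the one used for observed trial data.
* `fit_bivariate_models` (all covariates at once): damped Fisher scoring
  with the empirical Fisher information (sum of per-patient score outer
  products) as curvature, fully vectorized across covariates.  This is
  what makes 10 folds x 100 covariates x hundreds of simulation
  replicates affordable on one CPU.  The reduced two-term design has a
  dedicated fast path that avoids stacked tensor contractions.

Both start from the per-margin univariate logistic MLEs with
`log psi = 0` — the exact MLE of the factorized model — and both floor
cell probabilities at 1e-12 inside the likelihood.  Convergence requires
the gradient max-norm below `1e-6 * n`; a fit that stalls, diverges, or
ends on the `log psi` bound is flagged, and flagged covariates contribute
zero to risk scores so the cross-validation pipeline is total.  Tests
assert that the two routes agree and that both recover known coefficients
from simulated data without bias.

## Cross-validated risk scores and clustering

Patients are split into `r = 10` random folds of near-equal size.  For
each fold, every covariate's single-covariate model is fitted on the
other folds, and each held-out patient receives the score pair
`(sum_j b1_j x_j, sum_j b2_j x_j)` built from the fitted
treatment-by-covariate interaction coefficients (a single sum for the
univariate CVRS).  Scores are raw weighted sums — no standardization.
Crucially, a patient's own outcomes never enter the fits that score them;
a test corrupts one patient's outcomes and verifies their score is
untouched.

Within each test fold the scores are partitioned by k-means (Lloyd, 10
restarts, seeded; scikit-learn's implementation, whose empty-cluster
relocation to the farthest points matches the intended degenerate-input
behaviour).  Raw k-means labels are arbitrary, so each fold's clusters
are mapped to canonical labels before memberships are pooled:

* `k = 2`: the centroid with the larger component sum is the sensitive
  cluster (label 2);
* `k = 4`: coordinates are split at the midpoint of the extreme
  centroids and quadrants read as 1 = low/low, 2 = high on the outcome-2
  score only, 3 = high on the outcome-1 score only, 4 = high/high.  If
  the quadrant pattern is not one-to-one the centroids are ranked by
  component sum (middle pair ordered by the second coordinate), and the
  fold is recorded in `fallback_folds` — a useful diagnostic that the
  scores support fewer than four clusters.

The same derived seed drives k-means in every fold, so pooled assignments
do not depend on fold numbering.  Per-fold clustering (rather than
pooling scores first) is kept deliberately, matching the design as
published even though pooling might be more stable at `N/r ≈ 40` points
per fold.

The marginal-CVRS comparator runs the univariate design on each outcome
separately (k = 2 each) and crosses the memberships into four groups.
`weighted_score` collapses a bivariate score to `w1*RS1 + w2*RS2` when a
single ranking with pre-specified outcome weights is wanted.

## Testing strategy

The overall two-sided level `alpha = alpha1 + alpha2` (default
0.04 + 0.01 = 0.05) is split between a pooled two-proportion z-test
between arms in all patients (level `alpha1`) and Fisher's exact test
between arms within the predicted sensitive cluster (level `alpha2`); the
trial is positive if either rejects.  A sensitive-group test with an
empty or single-arm cluster is recorded as a non-rejection.  The
treatment-by-sensitivity interaction can also be tested by a Wald test in
the logistic model `y ~ t + s + t:s`, but because the sensitivity labels
come from cross-validation the asymptotic null is unreliable; the
permutation wrapper re-runs the entire scoring/clustering pipeline on
treatment-permuted data (fresh folds per permutation, all seeds derived
from one master seed) and reports `(1 + #{p* <= p0}) / (1 + n_perm)`.
Permuting treatment labels — rather than outcomes — preserves the
covariate–outcome joint distribution, which is the null of no
treatment-by-subgroup interaction.  Non-evaluable permuted p-values count
as 1, which is conservative.

## Scenario simulator

The generator emulates a two-arm trial (1:1 randomization, arm sizes
within one patient) with 100 baseline covariates of which 10 are
informative per outcome, sharing `n_overlap` columns (default 5).
Patients belong to latent clusters; a cluster sensitive to outcome `i`
has its outcome-`i` signature columns drawn from an equicorrelated
Gaussian with mean 1 and variance 0.25, while in other patients those
columns are nearly degenerate (mean 0, variance 0.01); the remaining
columns are mean-0, variance-0.25 noise.  One preset family has two
clusters (nonsensitive 80–90%, sensitive-to-both 10–20%) and one has four
clusters at 70/10/10/10% (low/low, high on outcome 2, high on outcome 1,
high/high); the correlated preset draws all 100 columns from a single
equicorrelated Gaussian with pairwise correlation 0.4; the null preset
keeps the covariate structure but makes every response rate equal.

Responses are Bernoulli draws from per-(cluster, arm) rates: 0.25
everywhere on the control arm and the configured per-cluster pair of
rates on the experimental arm, the two outcomes conditionally independent
given cluster and arm.  This reproduces every published per-cluster rate
and power exactly and keeps the covariates informative of cluster
membership, which is all the scoring pipeline uses.  What it does not
reproduce is a marginal outcome correlation that varies with the number
of overlapping covariates: conditional independence given cluster makes
the treatment-arm correlation a fixed function of the cluster mixture.
No generator consistent with the published per-cluster rates can vary
that correlation through the overlap alone (a cluster sensitive to one
outcome only would need the shared columns simultaneously elevated and
suppressed), so the overlap's effect appears here — as in practice it
must — through the geometry of the risk scores: with 9 of 10 columns
shared, the two middle clusters become indistinguishable and the
four-cluster analysis collapses to two groups, which the tests verify.
Real data differ from this generator in having covariate main effects,
non-Gaussian covariates, and residual outcome dependence within
subgroups, so passing tests demonstrate correctness of the machinery and
calibration under the stated mechanism, not performance on any
particular trial.

## Operating characteristics

`run_operating_characteristics` repeats simulate → score (reduced model,
matching the generator) → cluster → test over seeded replicates and
reports, per outcome: the trial-population power, the per-cluster
sensitive-group power, and the overall (either-test) power as the
per-replicate OR — which dominates both component powers by construction;
the independent-tests approximation `p_tp + (1-p_tp)*p_sens` is exposed
separately as `overall_power_formula`.  Selection quality is the
per-cluster sensitivity/specificity against the simulation truth, taking
each cluster in turn as the assumed sensitive group.  The estimated
response rate of a cluster is the observed rate among experimental-arm
patients assigned to it, which is the reading consistent with the
published summaries (control patients sit at the control rate
regardless).  Replicate seeds derive deterministically from the master
seed; replicates with a non-evaluable sensitive-group test count as
non-rejections with denominators fixed.

Monte-Carlo standard errors are binomial (`sqrt(p(1-p)/R)`) for rejection
rates and empirical (`sd/sqrt(R)`) for means.  The acceptance script runs
100 replicates per scenario (200 for the null scenario, where the
quantity of interest is a ~0.05 rejection rate); the test suite re-runs
the same pipeline at 30–100 replicates with module-scoped fixtures so one
simulation serves every check that the corresponding published table
derives from.  These sizes put the binomial 3-SE band at roughly ±0.15
for mid-range powers and ±0.06 for the null rejection rates, which is the
resolution at which the published values are verified.

## Numerical and design choices

* Cell floor 1e-12; linear predictors clipped at ±30 inside optimization.
* `log psi` bounded to ±10; hitting the bound flags non-convergence.
* k-means: 10 restarts, Lloyd; the same seed in each fold.
* Pooled two-proportion z without continuity correction (the plain
  difference-of-proportions test); Fisher two-sided p as the sum of table
  probabilities not exceeding the observed table's.
* Fold indices are 0-based internally; cluster labels 1-based.
* Optional covariate prefiltering (keep covariates whose training-fold
  univariate interaction Wald p falls below a threshold) is available but
  off by default, matching the design's primary usage.
* The full model (with main effects) is the default for observed data;
  simulations use the reduced model to match their generating mechanism.

## Known limitations

* Binary endpoints only; no survival or continuous outcomes.
* k restricted to 2 or 4 with fixed canonical semantics; no automatic
  choice of k and no cluster merging.
* The simulator does not reproduce overlap-driven marginal outcome
  correlations (see above) nor covariate main effects.
* Standard errors from the single-covariate fit are Wald/curvature-based
  and intended for diagnostics, not formal inference after selection.
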