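# Methods

`confsel` studies a concrete estimation question: when a set of potential
confounders has been prespecified from background knowledge, does pruning it
by backward elimination ever beat simply fitting the full outcome model, in
mean-squared-error terms, for the causal effect of a binary exposure `A` on a
binary outcome `Y`?  The package implements the estimation toolkit (Firth /
FLIC logistic regression, standardization, bootstrap inference), the
synthetic data-generating mechanisms, the Monte-Carlo evaluation engine, and
a closed-form linear-model account of the underlying bias-variance
trade-off.

## Models and estimands

Data are generated from

    A_i ~ Bernoulli(expit(alpha0 + beta_LA . L_i))
    Y_i ~ Bernoulli(expit(gamma0 + theta A_i + beta_LY . L_i))

with continuous covariates `L`.  `theta` is therefore the conditional log
odds ratio (log cOR) by construction.  The marginal estimands are defined by
standardization: with `p1_i`, `p0_i` the model-predicted outcome
probabilities with exposure set to 1 and 0 for every subject,

    log mRR = log(mean p1 / mean p0)
    log mOR = logit(mean p1) - logit(mean p0)
    mRD     = mean p1 - mean p0.

True marginal values per scenario come from the same formulas applied to a
large covariate sample (default N = 1,000,000; only the scalar projections
`beta_LA . L` and `beta_LY . L` matter, and they are exactly bivariate
normal, so no 24-column sample is ever materialized).  The marginal OR is
noncollapsible: |log mOR| < |log cOR| whenever covariates predict the
outcome, even without confounding.

## Estimation

**Firth penalized logistic regression.** Maximizes
`l(beta) + 1/2 log |X'WX|` by modified-score Newton iteration with
step-halving (max 50 iterations, up to 5 halvings, convergence when the
largest modified-score component falls below 1e-6).  This removes the
leading small-sample bias of ML and keeps estimates finite under
separation — essential at event fraction 0.03 with 24 covariates.  Matrix
solves use Cholesky factorizations of the information; the covariance is
`inv(X'WX)` at the optimum.

**FLIC.** Slopes are fixed at the Firth estimates and the intercept is
re-estimated by plain ML with the rest of the linear predictor as offset, so
the mean fitted probability equals the observed event fraction — the right
basis for standardized risks (the raw Firth fit shifts predicted risks
toward 1/2).  The reported covariance keeps the Firth slope block and
replaces the intercept variance by the offset-model value `1/sum(w)`; the
intercept-slope covariances are inherited from the Firth fit and are
approximate.

**Penalized LR tests and profile intervals.** Both fix coefficients and
re-maximize the penalized likelihood *keeping the full-model penalty*.
Comparing models that each carry their own Jeffreys penalty is not a valid
test: the penalty contributes roughly `1/2 log` (information) per parameter,
which would masquerade as evidence for keeping any covariate (a pure-noise
covariate at n = 1000 would receive p ≈ 0.02).  Confidence-interval
endpoints solve the chi-squared(1) profile-deviance equation by bracketed
root-finding; the test statistic is floored at zero.

**Backward elimination.** Classical one-at-a-time removal: at each step the
removal p-value of every remaining candidate is the penalized LR test of
that single coefficient; the largest p above the threshold (default
alpha = 0.157, approximating AIC selection) is removed, ties broken by the
lowest column index, no re-entry.  The intercept and exposure are forced to
stay.  Wald p-values are available as an option.  For speed, the per-step
p-values are computed for all candidates simultaneously by a batched tensor
Newton that is numerically identical (agreement to 1e-9, cross-checked in
the test suite) to the one-at-a-time profile fits, which remain as the
fallback path.

**Bootstrap inference.** Percentile intervals from B = 500 row-resamples by
default.  Three modes: refit the full model; refit the covariate set
selected once on the original data ("selected-model", invalid after
selection); or re-run the entire elimination inside every resample
("global").  Non-convergent resamples are dropped and counted; more than
10% dropped raises an error.  RCB and RMSDR compare globally re-selected
bootstrap estimates `t_b` with the original full-model estimate:
`RCB = 100 (mean t_b - t_full)/t_full` and
`RMSDR = rms(t_b - t_full)/SE_full`, with `SE_full` the model-based Wald
standard error for the log cOR and the bootstrap SD of full-model resamples
for marginal estimands (both available as switches; the literature leaves
the exact denominators open, so the choice is stated rather than attributed).

## Data-generating mechanisms

**Experiment 1** (proof of concept): one standard-normal covariate, null
exposure effect, n in {60, 120}, event fraction in {0.5, 0.2}, and
`beta_LA, beta_LY` on the six-point grid {0, 0.1, ..., 0.5} — the only
uniform grid consistent with 144 scenarios over the stated [0, 0.5] range.

**Experiment 2**: 24 covariates, equicorrelated multivariate normal
(correlation 0.3, drawn exactly via a one-factor representation); 12 fixed
confounders at (log 1.05, log 1.05); four exchangeable sets of three
covariates each assigned a pair from {0, log 1.05, log 1.2}^2, enumerated as
sorted multisets — 495 distinct assignments, times theta in {0, log 1.5},
expected events in {50, 200} and event fraction in {0.2, 0.03}: 3960
scenarios, n in {250, 1000, 1667, 6667}.

**Calibration.** The exposure-model intercept targets prevalence 0.5 (a
symmetric default; the target is a configuration knob) and the outcome
intercept targets the event fraction marginally over the induced exposure
distribution.  Both are solved by Brent root-finding on a frozen-seed
Monte-Carlo sample (10^6 draws) of the two Gaussian linear-predictor
projections; the maps are strictly increasing, achieved values match
targets to well below 1e-4 on the calibration sample and to MC error
(~5e-4) on independent samples.

**Seeding.** Every dataset is reproducible from
`(root seed, replicate index, scenario id)` through `numpy` seed sequences,
so per-scenario results are independent of execution order and a partially
completed grid resumes bitwise-identically.

## Performance measures

Per scenario and strategy (full / backward / unadjusted), bias, variance
(n−1 denominator) and MSE (mean squared deviation from the truth) are
computed from the same replicate vector, so
`mse = bias^2 + variance * (R-1)/R` holds exactly.  Relative efficiency is
MSE(backward)/MSE(full).  Non-convergent replicates are dropped and
counted.  Coverage (optional) is evaluated for the full model: Wald and
profile-penalized-likelihood intervals for the log cOR and percentile
bootstrap (B = 200, a reduced count chosen for tractability) for the
log mRR.

**The omission inequality.** Omitting covariates pays in MSE exactly when
`bias_omit^2 < var_full - var_omit`.  The Monte-Carlo check of this
inequality uses the debiased squared-bias estimator
`(mean estimate)^2 - var/R`, since the naive plug-in squared bias is
inflated by `var/R` — irrelevant at 10,000 replicates but decisive at
desk-scale replicate counts.  Even debiased, the *indicator* remains noisy:
variance-difference estimates flip borderline scenarios toward "fails", so
the proportion of scenarios satisfying the inequality is biased downward at
small R (measured on the 144-scenario grid for the log cOR: ~79-82% at
R = 500, ~87% at R = 2000, ~87.5% at R = 10,000).  The headline run in
`scripts/acceptance.py` therefore uses R = 10,000 replicates per scenario
— affordable on one CPU because Experiment-1 fits are vectorized across
replicates (a batched Firth/FLIC Newton agreeing with the scalar fits to
1e-8); the test suite uses R = 2000 to stay within its time budget.

## Problem sizes used in the shipped tests

The full 3960-scenario, 1000-replicate Experiment-2 grid is not desk-scale
(roughly a CPU-month with elimination over 24 Firth-fitted candidates).
The test suite instead runs, as the package's own desk-scale design:

* Experiment 1 in full (144 scenarios, 2000 replicates in the suite;
  10,000 in the standalone reproduction script);
* a stratified 20-scenario, 200-replicate parameter-recovery run (full
  model unbiased for theta; crude estimator biased upward under
  confounding; noncollapsibility ordering);
* a stratified 40-scenario backward-elimination run with replicates
  shrinking in n (16/10/5/3 for n = 250/1000/1667/6667), using paired
  replicates so the MSE ratio is stable; asserted through the sample median.

`examples/` and `engine.run_grid` (checkpoint/resume, optional joblib
parallelism) scale the same code up to the full grid for users with the
compute.

## What the generator does and does not emulate

Covariates are exactly multivariate normal with a single exchangeable
correlation; real covariate sets are mixed-type, skewed and block-
correlated.  All effects are linear on the log-odds scale, the covariate set
contains no mediators or colliders, and there is no unmeasured confounding,
so passing tests certify the estimation machinery and the bias-variance
phenomenology under the assumed mechanism — not robustness to
misspecification.

## Known limitations

* FLIC intercept-slope covariance entries are inherited from the Firth fit
  (approximation; slope inference is unaffected).
* The bootstrap drops non-convergent resamples rather than imputing them;
  at event fraction 0.03 with small B this can shift percentile endpoints
  slightly.
* `theory` uses expected-information OLS variances; at n below ~30 the
  finite-sample inflation of the slope variance (order 1/n) is visible
  against the simulation oracle.
* Augmented backward elimination, lasso-type selection, propensity-score
  (exposure-model) selection, IPW/TMLE estimators and nested-loop plotting
  are out of scope.
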