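# Methods

This note documents the statistical procedures implemented in `acehealth`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data tests do and do not establish.

## Estimation model

Each of the seven binary outcomes (metabolic syndrome, hypertension,
asthma, depression, anxiety, suicidal ideation, drug use) is modeled by a
modified Poisson regression: a log-link Poisson working likelihood fit to
the 0/1 outcome, so that `exp(β)` is a risk ratio rather than an odds
ratio. The working model is deliberately misspecified in its variance
(Poisson instead of Bernoulli); all inference therefore uses a robust
covariance.

**Fitting.** Weighted IRLS (Newton) starting from
`β₀ = log(weighted prevalence)` with all other coefficients at zero.
Step-halving (up to 10 halvings) guards the update whenever the weighted
working objective increases, since the log link on binary data can step
outside the stable region. Convergence is declared when the relative
coefficient change falls below 1e-10 (max 100 iterations). A secondary
stop triggers when the objective change falls below 1e-12 relative: this
handles quasi-separated cells — e.g. a race × exposure cell with zero
cases, plausible in a group of ~70 with a rare outcome — where the
coefficient legitimately drifts to −∞ while the fit plateaus, the same
behavior standard GLM deviance criteria accept. Fitted risks above 1 are
possible under the working model; they are flagged on prediction, never
clipped.

**Design-based variance.** The sandwich `V = B M Bᵀ`-style covariance uses
the inverse weighted information as bread and, as meat, the between-cluster
covariance of weighted score totals computed within stratum with the
`n_h/(n_h − 1)` correction and summed over strata (Taylor linearization
for a stratified cluster design, no finite-population correction — no
sampling-frame information is assumed). The product is assembled in
square-root form (`(B M^{1/2})(B M^{1/2})ᵀ`) so the result is positive
semi-definite by construction even when the information matrix is nearly
singular under separation. Strata with a single cluster are treated as
certainty strata by default (zero variance contribution, with a warning);
an error mode is available.

## Multiple imputation

The source data's missingness burden is heavy (55% of participants missing
an ACE component, 21% a covariate, 40% an outcome), so the pipeline
completes data by chained equations before any derivation: binary fields by
ridge-stabilized logistic fits with a normal parameter draw and Bernoulli
imputation; ordinal fields (parental education, support items) by
proportional-odds draws, falling back to a rounded linear draw if the
ordinal fit is degenerate; continuous fields by Bayesian linear draws with
posterior-predictive noise. All outcomes, the survey weight, race, age and
sex enter every component model as predictors; weights enter as a
*predictor*, not as fitting weights, the common pragmatic choice for a
weight-naive imputation engine (configurable). Chains are initialized by
hot-deck draws from observed marginals and cycled five times by default
(cap 10). The engine is intentionally simple — it is a stand-in for
heavier MI machinery, adequate for MCAR and the mild MAR mechanisms the
generator produces — whereas the pooling rules, which drive all reported
intervals, are exact:

    β̄ = mean(β),  W = mean(V),  B = cov(β),  T = W + (1 + 1/M) B,
    ν_j = (M − 1) (1 + W_jj / ((1 + 1/M) B_jj))².

Terms with degenerate between-imputation variance receive a large-df
sentinel so a normal reference applies. ACE components are imputed at
component level; the 0–10 score is summed and dichotomized (≥ 4 = elevated)
only afterwards, and the derivation raises if it ever sees a missing
component, so a skipped imputation cannot pass silently.

## Derived variables

* **ACE score** — sum of ten binary adversity components; exposure is
  score ≥ 4.
* **Metabolic syndrome** — positive in ≥ 3 of 5 categories: (1) blood
  pressure ≥ 130 systolic or ≥ 80 diastolic mmHg, or diagnosis, or
  medication; (2) waist > 102 cm (male) / > 80 cm (female);
  (3) triglycerides in the top 3 (male) / top 2 (female) weighted deciles;
  (4) HDL in the bottom 2 (male) / bottom 3 (female) weighted deciles;
  (5) HbA1c > 5.7%, or anti-diabetic medication, or diagnosis.
  Hypertension as a stand-alone outcome reuses category (1).
* **Covariates** — age; sex; the max of the two parents' five-level
  education; income divided by √(household size); the mean of five 1–5
  support items; the mean of five tract-level disadvantage proportions
  (each in [0, 1]).

Weighted quantiles use the left-continuous inverse of the weighted
empirical CDF (no interpolation), matching `numpy`'s `inverted_cdf` method
at unit weights; "top-k-decile" membership is value ≥ boundary and
"bottom-k" is value ≤ boundary. Decile cutoffs are sample-relative: they
are recomputed within each imputed dataset on the pregnancy-excluded
analysis sample (both choices configurable, since the ordering of
exclusion, imputation and cutoff estimation is not externally fixed).

## Interaction surfaces

With Multiracial as referent (White available for sensitivity), the
pipeline reports per group `g`:

* within-group RR `exp(β_e + γ_g)`, CI from the linear-combination
  variance under the pooled total covariance (normal reference by default;
  a Rubin-df t reference is available);
* interaction ratio `exp(γ_g)`, which by the model identity equals
  `RR_g / RR_referent` — the package enforces this identity to 1e-12;
* RERI `= RR_g1 − RR_g0 − RR_ref1 + 1` (all cell ratios sharing the
  doubly-unexposed baseline), converted to the interaction contrast
  `IC = RERI × R00` and reported as excess cases per 1000.

`R00` is the model-predicted risk at the referent-race, low-ACE cell with
covariates at their survey-weighted means (a reference-profile
standardization). A marginal alternative — the weighted average predicted
risk over the actual doubly-unexposed rows — sits behind a flag; the two
agree exactly on saturated models and differ only through model
nonlinearity in covariates. This is the main recognized ambiguity in
RERI→IC conversion and the default is stated in every manifest.

Confidence intervals for excess cases are 2.5/97.5 percentiles of the
functional over `n_resamples` (default 10,000) multivariate-normal draws
of the coefficient vector with covariance `T`, drawn once after pooling
(per-imputation draws are configurable). Percentile rather than
bias-corrected intervals are used, and the draw is deterministic given the
seed. Note the sign logic: excess cases are negative exactly when RERI is
negative; a multiplicative interaction ratio below 1 does *not* by itself
determine the additive sign — the test suite pins this with constructed
counterexamples.

A caution for users comparing published tables of this design: the ratio
identity `interaction RR = RR_g / RR_ref` can disagree with independently
rounded table entries (a 1.03 vs 0.97 mismatch of this kind exists in the
source literature); this package enforces the identity and does not
reproduce rounding artifacts.

## Synthetic cohort generator

The generator emulates what the analysis assumes about the data, not the
source study's actual school-based frame:

* stratified cluster sampling (default 20 strata × 4 clusters), log-normal
  weights with mean 1 within stratum (dispersion 0.5) — positivity and
  heterogeneity are what the variance code needs, no weight distribution
  being externally specified;
* five race groups at the published weighted shares (74/17/3.2/0.6/5.8%,
  rescaled to sum to 1);
* ten exchangeable Bernoulli ACE components with a race-specific per-item
  probability solved by root finding on the binomial tail so that
  `P(score ≥ 4)` matches the published group prevalences (25/33/21/40/35%);
  only the dichotomized prevalence is externally constrained, so
  exchangeability is the neutral joint-distribution choice;
* outcomes drawn from a log-linear (log-binomial) risk model
  `risk = baseline × raceRR × aceRR^elevated × covariate multipliers`, so
  configured RRs are exactly the estimand of the analysis model and
  parameter recovery is a sharp test; generation refuses, naming the cell,
  if any implied risk exceeds 1. Default within-group RRs are the published
  adjusted estimates; default baseline risks and race main-effect RRs are
  set so marginal prevalences track the published descriptives. Covariate
  effects default to zero (the covariates are then pure noise in the
  model); nonzero log-RR effects on centred covariates are configurable;
* a biomarker panel at plausible young-adult levels to exercise the
  composite classifiers, plus a pregnancy indicator (females only, 7%) to
  exercise the biomarker-model exclusion rule;
* missingness: a class rate is the fraction of rows with at least one
  missing field of that class (matching how the burden is reported for the
  source data: 55/21/40% for ACE components, covariates, outcomes).
  Selected rows mask each field of the class with probability 1/2 (at
  least one forced). MCAR by default; a MAR option tilts selection by race
  and low parental education while preserving the marginal rate. Design
  variables are never masked.

What passing simulation tests shows — and does not. Recovery and coverage
results demonstrate that the estimator chain is correctly implemented for
data generated under its own assumptions (log-linear risks, exchangeable
components, independence of outcomes given race and covariates, MCAR/mild
MAR). They cannot establish robustness to the source data's real features:
informative school-based sampling, correlated adversity components,
outcome dependence, or strong MNAR missingness.

## Problem sizes and numerical defaults

Monte-Carlo checks use 200 replicate cohorts of n = 12,000 for parameter
recovery (matching the source sample size), 500 small replicates for Wald
coverage of the fit, and 200 MAR replicates for pooled-interval coverage,
each asserted within three Monte-Carlo standard errors; the test suite
uses reduced M (2–5) and smaller cohorts where only correctness, not
power, is at stake. Resampling CIs stabilize to within 2% of their
endpoints by 10,000 draws on reference fits. Known limitations: the
imputer is not fully proper for ordinal fields under fallback; certainty
handling of single-cluster strata understates variance; and AI/NA-sized
groups (~0.6% of the cohort) routinely produce quasi-separated cells whose
excess-case intervals are effectively unbounded — mirroring the very wide
intervals such analyses report on real data.
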