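# Methods

`calsim` estimates how much of the social gradient in childhood obesity
would remain if children's daily energy intake were changed by policy, and
simulates specific calorie-reduction interventions. This note records the
models, the synthetic data-generating process, the numerical choices, and
what the validation suite does and does not establish.

## Causal structure and estimands

One row per child. The exposure `A` is maternal occupational social class
at birth, coded by *disadvantage*: 0 = high class, 1 = mid, 2 = low. The
baseline confounder `C` is child ethnicity; the intermediate confounders
`L` (affected by `A`, affecting both mediator and outcome) are birthweight
category, child health, activity-score category and weekly TV-time
category. The mediator `M` is total daily energy intake (kcal/day) at age
7; the outcome `Y` is obesity at age 11 (optionally combined
overweight/obesity).

Two weighted logistic marginal structural models are fitted:

* **TDE** (total direct effect): `logit P(Y) = b0 + b_A·1[A]`, weighted by
  the stabilized exposure weight `w1 = P(A) / P(A | C)`.
* **CDE** (controlled direct effect): `logit P(Y) = b0 + b_A·1[A] + b_M·M`,
  weighted by `w1 · w2` with the stabilized mediator density-ratio weight
  `w2 = f(M | A) / f(M | A, C, L)`.

Prevalences come from marginal standardization: per-child predicted
probabilities at the child's own covariates, averaged overall and within
class, ×100. Intervention scenarios are scored by replacing each child's
`M` with its post-intervention value in the prediction step while keeping
the fitted CDE coefficients (re-fitting per scenario is available behind
`refit_per_scenario`, off by default: the scenario machinery re-estimates
predicted probabilities, not the outcome model).

Relative and absolute inequalities re-fit the model with class as a single
linear term, standardize fitted probabilities at the class extremes (class
forced to 0 and to 2 for every child), and report `RR = p_low/p_high` and
`RD = (p_low − p_high)×100`, so `RD = (RR−1)·p_high·100` identically.
Standardizing over the whole cohort is the default; within-group averaging
is available (`standardize="within_class"`).

A multiplicative exposure×mediator interaction is Wald-tested (robust
covariance) before the CDE fit; at p ≥ 0.05 the interaction term is
omitted. No additive-interaction correction is attempted — the model
family is deliberately the plain weighted logistic MSM. Known limitation:
when exposure and mediator both affect the outcome, an interaction must
exist on at least one scale; the CDE here, like the model it replicates,
ignores the additive one.

## Weights

* **w1** — numerator: marginal class frequencies; denominator: multinomial
  logistic regression of class on the baseline confounders (main effects).
  With all-categorical confounders a `method="saturated"` variant uses
  exact stratum frequencies, which is the MLE of the fully interacted
  model and identical to the logit fit for the single-confounder default.
  Positivity is checked up front: an exposure level missing from a
  confounder stratum raises an error naming the stratum.
* **w2** — both densities are homoscedastic Gaussians: means from linear
  models of `M` on `A` (numerator) and on `A, C, L` (denominator), SDs from
  the residuals. The numerator conditions on the exposure (standard
  stabilization for a CDE weight); a marginal numerator and a log-intake
  scale (`scale="log"`, better matched to right-skewed intake; the Jacobian
  cancels in the ratio) are options.
* **Trimming** — the product weight is winsorized at the 1st/99th
  percentile *values* (capping, not deletion: the analytic n must not
  change). Percentile bounds are order statistics (`lower`/`higher`
  interpolation). This choice is deliberate: an interpolated bound is not
  reproduced when the percentile is recomputed on the capped data, whereas
  an order-statistic bound is, making trimming exactly idempotent.
  Trimming w1 and w2 separately is available (`trim_target="separate"`).

Bootstrap confidence intervals for RR/RD resample children with
replacement and re-derive both weights inside every replicate (the weight
estimation step invalidates model-based SEs); 1000 replicates by default,
percentile intervals, non-convergent replicates dropped and counted. The
bootstrap inner loop re-implements the identical estimation steps in
vectorized numpy (stratum-frequency exposure model, least-squares density
models, Newton IRLS with deviance tolerance 1e-10); agreement with the
statsmodels route is asserted to ~1e-7 in the test suite.

## Intervention scenarios

All scenarios modify only the mediator vector. Shared machinery:

* **Eligibility**: everyone; the low-income flag; the obesity-at-7 flag; or
  intake strictly above the sex-specific EAR (estimated average
  requirement, 1649 kcal boys / 1530 kcal girls at age 7).
* **Uptake**: each eligible child is independently treated with the given
  probability (75% for the universal and low-income scenarios, 100% for
  the indicated and truncation scenarios), deterministically per seed.
* **Noise**: the intended per-child reduction is drawn
  `Normal(mean, (noise_cv·mean)²)`, truncated at zero so intake never
  increases. The noise scale is parameterized as a coefficient of
  variation of the intended reduction, default 0.25 — the variability
  magnitude was an open choice; it is logged in every scenario's summary.
  Noise is applied on the absolute-kcal scale.
* **Lower bound**: intake mean − 2·SD, pooled over sexes, computed once
  from pre-intervention intake. A child already below the bound is never
  reduced; a treated child starting above it is capped at the bound rather
  than redrawn.

Effects: `shift_to_ear_median` subtracts the sex-specific
(median − EAR) gap computed from the cohort in hand;
`proportional_reduction` subtracts a fraction of the child's own intake
(default 21.3%, the healthy-weight-loss recommendation of ~500 kcal/day
expressed against the adult EAR); `truncate_at_ear` sets intake exactly to
the EAR with no noise (a hard cap, not a behavioural intervention).

## Synthetic cohort generator

The study cohort is access-controlled, so the generator emulates its
*marginal* structure and provides a fully known *causal* structure:

* categorical confounders with mild class gradients, calibrated so the
  marginals reproduce the published analytic-sample descriptives (male
  51.9%; class 31.6/42.7/25.7%; non-white 4.3%; the four intermediate
  confounder distributions; low income 33.7%; obesity at 7 = 9.3%;
  obesity at 11 = 18.3%; combined overweight/obesity 34.4%);
* log-normal intake with sex-specific intercepts calibrated to the
  published sex medians (1732.4 / 1654.1 kcal) and a weak *positive*
  gradient toward the high class (the published, initially
  counter-intuitive pattern: highest reported intake in the highest
  class), log-scale SD 0.20 (≈20% CV, typical of diet-diary intake);
* logistic outcome and obesity-at-7 models with invented coefficients
  (class +0.12 per disadvantage unit; intake +0.06 per 100 kcal; small
  confounder effects) whose intercepts were fixed once by bisection on
  simulated prevalence at n = 400 000 and then frozen.

Because all confounders are categorical, the 216-cell confounder lattice
can be enumerated exactly, giving closed-form oracles:
`true_cde_curve/true_cde_oracle` (outcome probability under joint class
and intake interventions) and `true_tde_oracle` (class intervention only,
integrating the log-normal intake per lattice cell by 48-point
Gauss–Hermite quadrature).

What the generator does **not** emulate: enrolment and attrition,
missingness (synthetic cohorts are complete-case by construction; multiple
imputation is out of scope), diet-diary measurement error, the six-way raw
occupational coding, or the sampling design behind the published standard
errors. One known tension: with a single log-scale SD the generator
matches both sex medians exactly but reproduces the per-sex above-EAR
shares only approximately (59.7%/65.1% simulated vs 55.7%/70.7%
published); matching both moments per sex would require strongly
sex-specific dispersions. Consequently passing tests demonstrate correct
estimation under a *plausible* intake distribution, not a reconstruction
of the real cohort's tails.

## Numerical choices

* MSM fits: statsmodels GLM (binomial), IRLS, deviance tolerance 1e-8,
  |coefficient| > 50 treated as separation; HC1 covariance for the Wald
  interaction test.
* Exposure-model fit (w1): Newton, tolerance 1e-10 — tight enough that the
  saturated-model equivalence with g-formula standardization holds to
  machine precision on small cohorts.
* Weight-2 density scale defaults to kcal (per the homoscedastic-Gaussian
  working model); the mediator confounding in the default generator is
  mild, and parameter-recovery tests confirm the resulting CDE estimates
  track the exact oracle within Monte-Carlo error.
* Scenario draws, uptake and bootstrap all use `numpy.random.default_rng`
  with seeds derived from the run's master seed via `SeedSequence`; the
  whole pipeline is bit-reproducible.
* Displayed report tables round percentages to 1 dp and RR/RD to 2 dp
  (matching the precision of the results they mirror); JSON artifacts keep
  full precision.

## Validation problem sizes

Marginal checks use n = 50 000 (±1 percentage-point tolerances);
CDE parameter recovery uses 20 replicate cohorts of n = 50 000 compared to
the exact oracle within 2 Monte-Carlo SEs; bootstrap calibration uses 200
replicate cohorts of n = 5 000 with 500 draws each (coverage required in
90–98%); the null-control pipeline uses n = 30 000. These sizes were
chosen to keep Monte-Carlo error comfortably below the tolerances while
the full suite remains quick to run.
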