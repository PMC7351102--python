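# Methods

## Estimand and estimator

For a survival outcome, let Y_{k+1} indicate failure in interval (k, k+1],
Z_k the vector of time-varying covariates measured at k (including the
treatments), and V the baseline covariates.  The target is the
counterfactual risk by interval k* under a sustained strategy g, or the
counterfactual mean of a fixed outcome measured at end of follow-up K+1.
The estimator is the parametric g-formula by joint density modelling:
plug-in models for the covariate distribution and the outcome hazard/mean,
with the standardization integral approximated by Monte Carlo.

**Step 1 — fitting.**  The joint distribution of Z_k given history is
factorized in the user-declared covariate order; each factor gets a
parametric family (`covtype`) and a model formula over the current-time
values of earlier-ordered covariates, history features of any covariate,
baseline covariates, and the time index.  The outcome gets a pooled
logistic hazard model over all person-time (survival) or a single logistic
/ linear regression on the rows at K (end of follow-up); the competing
event, when modelled rather than treated as censoring, gets its own pooled
logistic hazard.  Covariate models are fitted on follow-up rows with
k ≥ 1 only, because at k = 0 the simulator resamples the observed baseline
joint distribution instead of simulating from a model.  When a follow-up
horizon k* < K+1 is requested, fitting is restricted to rows with k < k*.

**Step 2 — simulation.**  s baseline rows (covariates at k = 0 plus any
pre-baseline history) are resampled with replacement from the n observed
baseline rows (used exactly once each when s = n, the default).  At each
k ≥ 1, covariates are simulated one at a time in factorization order; at
every k (including 0) the *natural* value of each treated covariate is
recorded and then replaced by the strategy's assigned value, which is what
enters subsequent history features.  After each time step the outcome
hazard p̂_k (and competing hazard q̂_k) are evaluated on the simulated row.
Risks are accumulated analytically along each history —
R(k) = Σ_{t≤k} p̂_t Π_{j<t}(1−p̂_j), with the competing event resolved
*before* the outcome within an interval in the modelled case,
R(k) = Σ_{t≤k} (1−q̂_t) p̂_t Π_{j<t}(1−p̂_j)(1−q̂_j) — rather than by
simulating event indicators.  This removes one layer of Monte Carlo noise
and leaves the estimand unchanged.  The per-strategy estimate is the mean
over the s histories; end-of-follow-up estimates are means of the outcome
model's predictions at the final simulated row.

## Covariate families

| covtype | fit | draw |
|---|---|---|
| binary | logistic GLM | Bernoulli |
| normal | OLS; residual SD = √(SSR/df) | Normal, clipped to the observed covariate range |
| categorical | multinomial logit, reference = first observed level | inverse-CDF over fitted class probabilities |
| bounded_normal | response rescaled to [0,1] by the observed (min, max), then OLS | Normal on the [0,1] scale, clipped, back-transformed |
| zero_inflated_normal | logistic for I(Z≠0) + OLS on nonzero rows (same right-hand side) | Bernoulli indicator × Normal clipped to the nonzero range |
| truncated_normal | OLS | proper one-sided truncated-normal draw at the declared point/direction |
| absorbing | logistic on rows whose previous value is 0 | 1 forever once 1, else Bernoulli |
| categorical_time | none | deterministic interval index of k in declared cut points |

Clipping simulated normal-family values to the observed range prevents
runaway extrapolation over many simulated intervals; it is deliberate,
documented behaviour, and it biases fits slightly when the truncation
actually binds (the bounded-normal unit test allows for this).  The
bounded-normal response is rescaled only for fitting; predictors stay on
the natural scale on both the fitting and the simulation side, so the two
are consistent.  The zero-inflated linear part is fitted on the natural
scale.  `categorical_time` is a deterministic recode of k usable as a
predictor; no stochastic model is fitted for it.

## Formula grammar and history features

Formulas use patsy grammar plus numpy functions and a restricted cubic
spline `rcs(x, knots=(...))` with explicit knots (stateless, so fitted
designs re-evaluate identically on simulated data).  Three history
features with a fixed naming scheme are generated from the formulas
themselves (the largest referenced lag determines the lag depth r):

* `lag{i}_Z` — Z at k−i; 0 before the subject's first record.  Pre-baseline
  rows (negative time indices) count as records, so lags can reach into
  them.
* `cumavg_Z` — mean of Z over follow-up times 0..k (equals Z at k = 0).
  Pre-baseline values are excluded: the running average is defined on the
  follow-up window only, which is the minimal consistent reading when
  pre-baseline records exist.
* `lag_cumavg{i}_Z` — `cumavg_Z` at k−i; 0 for k < i.

The batch (fitting-side) and incremental (simulation-side) constructions
are property-tested for exact equivalence.  The 0 padding applies to
categorical covariates too; a lagged categorical without a 0 level
triggers a warning because the padding would act as an extra level.

## Strategies

A strategy is a list of (variable, rule, applicable times) components;
times default to all follow-up times, and the natural value is kept at
non-applicable times.  Rules: `static` (value vector over k), `threshold`
(clip the natural value to [min, max]), `natural`, and `custom` (a pure
callback receiving k, the simulated history so far, the natural values,
and an RNG handle — covering dynamic and random rules).  The natural value
of every covariate is always drawn first, even under static rules: this
makes natural-value-dependent rules well defined and means every strategy
consumes an identical random stream, so a threshold rule with infinite
bounds reproduces the natural course bit for bit under a shared seed.  The
natural course is always strategy 0 and the default reference for
ratio/difference contrasts.

## Random numbers

One master seed; baseline resampling and the per-strategy simulation use
`numpy.random.SeedSequence` children, with the *same* child stream for
every strategy (see above).  Simulation draws are vectorized across the s
histories per time step rather than giving each history its own
counter-based substream; since the simulation is single-threaded, results
are scheduling-independent, and bootstrap replicates (the parallel unit)
carry replicate-indexed substreams, so bootstrap results are invariant to
the worker count.

## Inference

Bootstrap replicates resample n subjects with replacement (whole subject
histories, preserving within-subject dependence), refit every model, and
rerun all simulations.  SEs are replicate standard deviations;
intervals are 95% percentile intervals, which respect the asymmetry of
ratio distributions where symmetric normal-approximation intervals would
not.  Replicates whose model fitting fails are excluded and counted.

## Nonparametric benchmarks

The natural-course diagnostics are a discrete-time product-limit risk
(interval hazard = events / at-risk, censored subjects leaving the risk
set after their last record; with modelled competing events the
Aalen–Johansen form Σ_t ĥ_t Π_{j<t}(1−ĥ_j−ĥD_j)), per-time covariate
means among subjects still under follow-up (unweighted — no censoring
weights), and the empirical end-of-follow-up mean over uncensored
subjects.  With saturated models on a discrete state space the parametric
natural-course estimate equals these benchmarks up to Monte Carlo error,
which the test suite verifies; agreement on real data supports, but never
guarantees, the absence of gross misspecification.

## Synthetic systems and what passing tests show

`gformula.dgp` ships five structural systems used as the test bed, with
defaults chosen once to emulate realistic epidemiologic studies: n = 2500
subjects, seven follow-up intervals, natural-course risks around 0.45–0.6
(binary end-of-follow-up mean near 0.09), a protective treatment, and
treatment–confounder feedback in every system:

* `survival_basic` — binary confounder, continuous confounder, continuous
  baseline covariate, binary treatment, logistic hazard with a linear time
  trend.
* `survival_compevent` — adds a competing-event hazard (~0.04/interval).
* `binary_eof` — binary/zero-inflated-continuous confounders, a
  *continuous* treatment (normal family) targeted by a threshold rule.
* `continuous_eof_categorical` — three-level categorical confounder
  (multinomial), continuous outcome at end of follow-up.
* `survival_toy` — fully discrete (binary confounder + treatment, no
  baseline covariate, K = 2, a treatment×confounder hazard interaction),
  small enough that the counterfactual truth is computable by exact
  enumeration of all paths.

Truth oracles are independent of the estimation engine: `enumeration` sums
the structural equations over all paths (discrete systems), `large_mc`
simulates ≥10⁵–10⁶ paths from the true equations under the strategy and
accumulates true-hazard risks, reporting its Monte Carlo SE.  The two
oracles are cross-checked against each other.

The recovery tests compare engine estimates (correctly specified formulas,
s = 10,000) with the truth within three combined standard errors, where
the combined SE is √(bootstrap SE² + truth-MC SE²) with B = 24 bootstrap
replicates — an honest estimate of the estimator's sampling variability,
which a simple binomial approximation understates for strategies that
extrapolate beyond the observed treatment distribution.  The enumeration
test compares the Monte Carlo standardization at s = 100,000 against the
exact g-formula sum computed from the *fitted* models by an independent
path-enumeration oracle in the test code.

What these systems do **not** emulate: informative censoring (generated
data have none, so the product-limit benchmark reduces to an empirical
CDF), measurement error, irregular visit times, and model misspecification
— passing recovery tests says the estimator is correct *when its models
are correct*, not that it is robust to misspecification on real data.

## Numerical choices and degenerate inputs

* Multinomial and logistic fits run through statsmodels; a design matrix
  with deficient rank raises an error naming the collinear terms, and a
  response without variation raises a "degenerate response" error rather
  than returning a vacuous fit.
* A covariate constant in its fitting rows is simulated as that constant.
* RMSE reporting: residual RMSE for continuous families (composite mean
  for zero-inflated), observed-minus-fitted-probability for binary, one
  minus the fitted probability of the observed class for categorical.
* Category draws use cumulative-probability inversion in fitted level
  order (tie-free); multinomial probabilities are computed with a
  max-subtracted softmax.
* Printed summaries use 7 significant digits; CSV/JSON exports keep full
  precision (re-read CSVs with `float_precision="round_trip"` for exact
  equality).

## Problem sizes

Defaults used throughout the examples, tests and the acceptance script —
n = 2500, s = 10,000, B = 20–24 bootstrap replicates, truth oracles at
3×10⁵ simulated paths — were chosen as representative analysis sizes for
this class of estimator; a full pipeline run at these sizes takes a few
seconds on one core, and the entire validation suite a few minutes.

## Known limitations

* Exact pre-baseline coding conventions beyond the −i..K indexing rule
  (and how running averages should treat pre-baseline values) are
  interpretations; lags may read pre-baseline rows, running averages do
  not.
* The nonparametric natural-course benchmarks are unweighted and can be
  biased under informative censoring; no inverse-probability-of-censoring
  weighting is implemented.
* Only percentile bootstrap intervals are provided (no BCa, jackknife, or
  delta-method variances).
* Covariate families are limited to the eight listed; no machine-learning
  plug-in learners, and no link functions beyond logit/identity.
* A priori deterministic knowledge of covariate distributions (restricting
  simulated values by known rules) is not supported.
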