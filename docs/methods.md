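# Methods

## The multi-state model

Individuals occupy one of six mutually exclusive states: community post
COPD diagnosis (`DX`), COPD-related ED visit (`EDC`), non-COPD ED visit
(`EDO`), COPD-related hospitalization (`HC`), non-COPD hospitalization
(`HO`), and all-cause death (`MO`, absorbing). All-cause rather than
cause-specific mortality is used because COPD is under-reported as a cause
of death. Seventeen direct transitions are allowed:

* **9 parametric arcs**, fitted as time-to-event models:
  `DX→{EDC, EDO, HC, HO, MO}`, `HC→{DX, MO}`, `HO→{DX, MO}`.
* **8 same-day arcs**: each ED state resolves into `{DX, HC, HO, MO}` by a
  multinomial draw, under the assumption that an ED stay never spans
  midnight (ED length of stay is 0 days). Deaths in the ED are therefore
  destinations of the multinomial, not a parametric arc.

The structure is a value (`TransitionStructure`), so reduced graphs (e.g. a
single `DX→MO` arc) are first-class and used throughout the tests to
compare the engine against closed forms.

### Clock convention

All parametric arcs use a clock-reset (semi-Markov) sojourn clock: time
since entry to the current state, with covariates frozen at entry. This is
the natural reading of "hospitalization → post-diagnosis" transitions and
matches standard practice for multi-state microsimulation from fitted
parametric models. A clock-forward alternative is available through the
left-truncation argument of `fit_survival` but is not the default.

## Survival families and the AFT convention

All six candidate families are expressed with a location μ on the log-time
scale, a positive scale σ where the family has one, and an extra shape for
gamma and generalized gamma (see `families.py` for the exact survival
functions). Covariates enter only the location: x·β shifts μ, multiplying
every quantile by e^{x·β}. Positive coefficients lengthen times
(protective); negative ones shorten them (harmful). The uniform AFT
parameterization is a design choice — it makes the six families freely
interchangeable per arc and keeps covariate effects comparable across
families; for the Weibull it maps to a proportional-hazards effect of
exp(−x·β/σ).

The generalized gamma uses the Prentice parameterization (μ, σ, q), which
nests Weibull (q = 1), log-normal (q = 0) and the gamma family (q = σ) at
interior parameter values, avoiding the boundary pathologies of the naive
parameterization. The gamma family itself is parameterized so that μ is the
log *mean* time (shape a, S(t) = Q(a, a·t·e^{−μ})), keeping the AFT
location interpretation exact.

Estimation maximizes the right-censored log-likelihood
Σ_events log f + Σ_censored log S (plus −log S(entry) under truncation)
over an unconstrained parameter vector (location, log σ, log shape or q,
β). Optimization is L-BFGS-B with tight tolerances and a Nelder-Mead
fallback; the coefficient covariance is the inverse observed information
(numerical Hessian), eigenvalue-clipped to PSD. Fits are validated in the
test suite against closed-form exponential MLEs and lifelines' independent
AFT fitters.

### Family selection

Each arc is fitted under all six families. The minimum-AIC family wins
unless a family with fewer free parameters is within **2** of the best on
*both* AIC and BIC, in which case the most parsimonious such family is
chosen (ties on parameter count broken by AIC). The threshold of 2 is the
conventional "indistinguishable" band for information criteria; the full
six-row comparison table is retained on the returned fit for reporting.
BIC uses n = number of sojourn records for the arc's origin state.

### Covariate encoding

One encoding map (`covariates.py`) is shared by every model: age in years
centred at 64 (the cohort median), female indicator, smoking (reference
*never*), rurality (reference *urban*), deprivation quintile (reference 1,
most advantaged), nine comorbidity indicators, and the four running event
counters as raw counts — 23 coefficients per model. Five predictors are
time-dependent: age and the counts of prior COPD/non-COPD ED visits and
hospitalizations, all re-evaluated at each state entry. Counters follow a
strictly-before-entry convention: a visit's own record does not include
itself, so a record's counter equals the number of earlier entries of that
type in the subject's own history.

## The microsimulation engine

Each subject starts at (day 0, `DX`) and is advanced by competing latent
clocks: at entry to a community or hospital state, one sojourn time is
drawn per exit arc from its covariate-adjusted distribution by inverse-CDF
sampling, the minimum wins, and times are rounded **up** to whole days
(ties between arcs broken by one extra uniform draw). ED states resolve
the same day via the multinomial model. Sojourns that would end after the
horizon censor the subject at the horizon in place. The default horizon is
14 years = 5,110 days, the observation span the model class is built for.

Covariates are frozen per sojourn: counters and age affect the *next*
sojourn, the simplest scheme consistent with how the models are fitted
(covariates at sojourn entry). Mid-sojourn ageing is ignored within a
sojourn; community sojourns are the only long ones, and the age gradient
across one sojourn is small relative to coefficient uncertainty.

Randomness is per-subject: a subject's stream is seeded by
(seed, …, subject id), so results are independent of cohort batching and
identical subjects get identical streams across paired scenario arms —
the common-random-numbers (CRN) property that makes a null counterfactual
contrast exactly zero and reduces contrast variance generally.

### Nested uncertainty

Parameter uncertainty is propagated by a two-level scheme: an outer loop
(default 200 replicates) draws every model's coefficient vector from a
multivariate normal (mean = estimates, covariance = inverse observed
information, on the estimation scale so transformed parameters stay in
range), and an inner loop re-simulates the whole cohort per draw. Bands
are pointwise empirical percentiles (2.5/97.5 by default) across
replicates, optionally smoothed by a monotonicity-preserving PCHIP spline
through thinned knots (25 by default); raw percentiles are always kept,
and reported numbers default to raw. Non-PSD covariances are rejected,
with an explicit `repair_non_psd` flag to project onto the nearest PSD
matrix instead.

## Outcome estimators

* **Survival / cumulative incidence.** Death is the only absorbing risk,
  so survival is the empirical complement of the death-time distribution
  and cumulative incidence is exactly 1 − S(t). Verified against
  Kaplan-Meier from lifelines.
* **Mean Cumulative Count.** Two estimators: a direct count (events at or
  before t over initial cohort size; valid under full follow-up, the
  simulation setting) and the Dong et al. estimator
  MCC(t) = Σ_{u≤t} Ŝ(u⁻)·d(u)/r(u) with Ŝ the overall-survival
  Kaplan-Meier, for tables with censoring. They coincide whenever the only
  censoring is the common horizon; this equivalence is a standing test.
* **Length of stay.** Mean days per hospital stay with a normal-theory CI;
  by default restricted to stays with a live discharge, the usual
  reporting convention.
* **Contrasts.** Absolute (a − b) and relative (100·(a − b)/b, NaN where
  b = 0 — flagged, never fabricated). Relative contrasts are computed
  replicate-wise and then summarized, so an empirical CI exists for
  quantities like "x% more ED visits"; for absolute contrasts the two
  orders coincide by linearity.

## Scenarios

*Stratified*: the cohort is partitioned by an observed categorical
predictor; outer parameter draws depend only on (seed, replicate), so all
strata share the same draws and between-stratum differences are not
inflated by parameter-sampling noise. *Counterfactual*: the identical
cohort is simulated factually and with exactly one predictor forced to a
new value, under CRN and shared outer draws; contrasts are computed
replicate-wise. Internal validation computes observed survival/MCC curves
from supplied histories and reports, per outcome and time point, whether
they fall inside the simulated bands (closed interval, so a value exactly
on the band edge counts as covered). Every scenario run can write a
manifest (config hash, seed, package version, collected warnings).

## The synthetic cohort generator

The real cohort's joint baseline distribution is not published — only its
marginal table. `generate_baseline` therefore draws from a **Gaussian
copula**: a latent multivariate normal with a configurable correlation
matrix, thresholded to the categorical marginals (upper-tail convention,
so positive latent correlation means co-occurrence with high correlates)
and transformed to the age marginal. Defaults:

* Marginals from the published baseline table (55.2% female, smoking
  43.9/39.1/17.0% current/former/never, deprivation quintiles renormalised
  from printed precision, nine comorbidity prevalences).
* Age: normal truncated to [35, 100] years with the parent (μ, σ)
  moment-matched so the truncated distribution has mean 63.9 and SD 13.8
  exactly — naive truncation of N(63.9, 13.8²) would inflate the mean by
  ~0.45 y.
* Correlations: modest positive latent correlations (0.10–0.20) between
  age and the age-graded comorbidities, zero elsewhere. This is a
  documented guess, not an estimate; any alternative can be supplied and
  serialized via `CohortSpec` YAML.

What the generator deliberately does **not** emulate: survey design and
weights, smoking-status misclassification, comorbidity–comorbidity and
smoking–deprivation dependence, and secular trends in diagnosis. Tests
passing on these cohorts therefore demonstrate correctness of the
machinery and calibration of the marginals, not fidelity of real-world
joint structure.

`default_true_model()` is a fully synthetic ground-truth parameter set
(family per arc following the best-fitting families reported for this
model class; day-scale locations chosen so event burdens are plausible —
~30% dead at 14 years, ~1.4 COPD ED visits per person, hospital stays of
order 10 days; harmful smoking/age coefficients on the acute and mortality
arcs). It exists so estimation, simulation and scenario machinery can be
exercised end-to-end with known parameters; its numbers are not estimates
from any real cohort.

## Numerical choices

* Closed-form identity tolerance 1e-8; quadrature comparisons 1e-6.
* |q| < 1e-8 is treated as the log-normal limit of the generalized gamma.
* Conditional sampling uses exact inverse-CDF truncation (U·S(t₀)), chosen
  over rejection sampling for exactness and constant cost.
* Zero-duration censored sojourns contribute log S(0) = 0; a zero-duration
  *event* (same-day exit) is nudged to half a day so log-time is defined.
* Daily rounding is ceiling-to-day, so every sojourn lasts at least one
  day and trajectories terminate within horizon-many steps.
* Infinite latent draws from heavy-tailed fitted arcs are treated as
  "beyond horizon" (censoring), never materialized.

## Problem sizes

Default study conditions are a 10,000-subject cohort, a 14-year horizon
and 200 outer replicates. The test suite exercises the same code paths at
reduced scale (cohorts of 80–10,000, 2–10 outer replicates) chosen so the
Monte Carlo tolerances in each test — typically three standard errors —
remain binding; the acceptance checks state their sizes explicitly
(n = 5,000 sojourns for recovery, 50 selection repeats, n = 10,000 for
engine-vs-closed-form and sampling KS tests).

## Known limitations

* No frailty/random effects, time-varying coefficients within a sojourn,
  interval censoring, or spline-based flexible baselines.
* The multinomial and parametric models share one covariate set; no
  per-arc variable selection.
* LOS confidence intervals are normal-theory, not replicate-based, when
  computed from a single trajectory set.
* The published per-transition coefficient estimates for the motivating
  cohort are not redistributable here; the shipped ground truth is
  synthetic, so absolute event rates are illustrative only.
* Costs, quality-of-life weighting and capacity constraints are out of
  scope.
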