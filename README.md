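# copdsim

Multi-state parametric survival modelling and individual-level
microsimulation of life after a COPD diagnosis.

People living with chronic obstructive pulmonary disease move between the
community, emergency departments, hospital wards and — eventually — death,
with COPD exacerbations and competing comorbid conditions both driving the
traffic. Policymakers and health economists who want to target
interventions (say, smoking-cessation programmes at newly diagnosed
smokers) need models that handle **competing risks**, **recurrent events**
(multiple ED visits and admissions per person) and **time-dependent risk
factors** (age, accumulated event history) at the individual level.
`copdsim` provides the full pipeline for that problem class:

1. **Multi-state model.** Six mutually exclusive states — community post
   diagnosis (`DX`), COPD-related ED visit (`EDC`), other ED visit (`EDO`),
   COPD-related hospitalization (`HC`), other hospitalization (`HO`), death
   (`MO`) — joined by 17 direct transitions: 9 time-to-event arcs plus
   same-day multinomial resolution of each ED visit into community,
   hospital or death.
2. **Estimation.** Each time-based arc is fitted cause-specifically by
   maximum likelihood under six candidate accelerated-failure-time (AFT)
   families — exponential, Weibull, log-normal, log-logistic, gamma,
   generalized gamma — with a shared 18-predictor covariate set
   S(t | x) = S₀(t · e^{−x·β}) and per-arc family choice by AIC/BIC with a
   parsimony rule. ED destinations use a multinomial logit.
3. **Microsimulation.** A competing-clocks Monte Carlo engine (one latent
   sojourn draw per exit arc, minimum wins, daily rounding) with covariates
   re-evaluated at every state entry, and two-level nested uncertainty:
   outer multivariate-normal draws of all model coefficients, inner
   whole-cohort simulation, giving empirical 95% confidence bands.
4. **Outcomes and scenarios.** Survival, the Mean Cumulative Count (MCC,
   the Dong et al. extension of Nelson's mean cumulative function,
   MCC(t) = Σ_{u≤t} Ŝ(u⁻)·d(u)/r(u)) per event type, hospital length of
   stay, and stratified or counterfactual scenario contrasts under common
   random numbers.

A Gaussian-copula cohort generator calibrated to the published baseline
table (n = 14,416 Ontario cohort marginals: mean age 63.9 y, 55.2% female,
43.9% current smokers, …) and a clearly labelled synthetic ground-truth
parameter set make every stage testable without any data access.

## Worked example

```python
import copdsim as cs

cohort = cs.generate_baseline(seed=1, n=2000)
model = cs.default_true_model()          # synthetic ground-truth parameters
trajectories = cs.generate_histories(cohort, model, seed=2)

grid = cs.default_grid()                 # monthly grid to 14 years
curves = cs.cohort_outcomes(trajectories, grid)
los = cs.los_summary(trajectories, "HC", discharged_alive_only=True)

print(f"14-year all-cause survival: {curves.survival[-1]:.3f}")
print(f"MCC of COPD-related ED visits at 14 y: {curves.mcc['copd_ed'][-1]:.2f}")

smokers = cohort[cohort.smoking == "current"].reset_index(drop=True)
cfg = cs.ScenarioConfig(kind="counterfactual", variable="smoking",
                        value="former", seed=3, n_outer=10)
res = cs.run_counterfactual(smokers, model, cfg)
rel = res.contrasts["relative"]["copd_ed"]
```

Output (the counterfactual pair takes about a minute at this size):

```
14-year all-cause survival: 0.689
MCC of COPD-related ED visits at 14 y: 1.43
MCC of COPD-related hospitalizations:  0.46
COPD hospital LOS (discharged alive): 11.97 d (95% CI 11.46-12.47, 866 stays)
non-quitters vs quitters, COPD ED visits at 14 y: +54.1% (95% band 49.7 to 60.8%)
```

Reading this: under the synthetic ground-truth model, 68.9% of the cohort
is still alive 14 years after diagnosis and the average person has
accumulated 1.43 COPD-related ED visits; COPD admissions that end in a
live discharge last about 12 days. The counterfactual run re-simulates the
*same* current smokers with only smoking status switched to "former"
(common random numbers, identical parameter draws), so the +54% excess in
ED visits among non-quitters isolates the smoking effect built into the
generating model.

The same pipeline is scriptable from the shell:

```bash
copdsim generate-cohort --n 10000 --seed 1 --out-dir run/
copdsim simulate-histories --cohort run/cohort.csv --seed 2 --out-dir run/
copdsim fit --cohort run/cohort.csv --histories run/histories.csv --out-dir run/fits
copdsim scenario --config scenario.yaml --cohort run/cohort.csv --params run/fits
```

`fit` writes delimited parameter tables (estimate/standard-error rows plus
a covariance file per transition) that `simulate`, `scenario` and
`validate` read back, so externally published coefficient tables in the
same format can be dropped in directly.

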