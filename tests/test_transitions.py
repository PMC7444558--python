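"""Dataset construction, cause-specific fitting, family selection, multinomial."""

import collections

import numpy as np
import pandas as pd
import pytest

import copdsim as cs
from copdsim.covariates import COEFFICIENT_NAMES
from copdsim.families import DistributionFamily, DistributionParams, sample_time
from copdsim.states import DX, EDC, EDO, HC, MO, StructureError, Trajectory
from copdsim.transitions import (
    InestimableError,
    build_transition_dataset,
    ed_records,
    fit_multinomial,
    fit_parametric,
    fit_survival,
    predict_destination_probs,
    read_parameter_tables,
    select_family,
    sojourn_records,
    write_parameter_tables,
)


def _profile_frame():
    return pd.DataFrame([{
        "subject_id": 1, "age": 64.0, "female": 1, "smoking": "current",
        "rurality": "urban", "deprivation": 1,
        **{c: 0 for c in cs.covariates.COMORBIDITIES},
    }])


class TestBuildDataset:
    def test_bookkeeping_example(self):
        """DX(0)->EDC(100)->DX(100)->MO(500): two DX sojourns, one ED record,
        with the COPD-ED counter visible only after the visit."""
        tr = Trajectory(1, [0.0, 100.0, 100.0, 500.0], [DX, EDC, DX, MO], horizon=5110.0)
        rec = build_transition_dataset([tr], cohort=_profile_frame())
        soj = sojourn_records(rec)
        assert len(soj) == 2
        first = soj.iloc[0]
        assert (first.entry_day, first.exit_day, first.to_state) == (0.0, 100.0, EDC)
        assert first.n_copd_ed == 0
        second = soj.iloc[1]
        assert (second.entry_day, second.duration, second.to_state) == (100.0, 400.0, MO)
        assert second.n_copd_ed == 1
        ed = ed_records(rec)
        assert len(ed) == 1 and ed.iloc[0].to_state == DX
        assert ed.iloc[0].n_copd_ed == 0  # strictly-before-entry convention

    def test_censored_record(self):
        tr = Trajectory(1, [0.0], [DX], horizon=1000.0)
        rec = build_transition_dataset([tr], cohort=_profile_frame())
        row = rec.iloc[0]
        assert not row.event and pd.isna(row.to_state) and row.duration == 1000.0

    def test_unknown_arc_named_in_error(self):
        tr = Trajectory(1, [0.0, 50.0, 60.0], [DX, HC, EDC], horizon=100.0)
        with pytest.raises(StructureError, match="HC->EDC"):
            build_transition_dataset([tr], cohort=_profile_frame())

    def test_counts_match_brute_force_tabulation(self, small_trajectories):
        """Per-arc record counts equal an independent transition tabulation."""
        rec = build_transition_dataset(small_trajectories)
        got = (
            rec[rec.event].groupby(["from_state", "to_state"]).size().to_dict()
        )
        brute = collections.Counter()
        for tr in small_trajectories:
            for a, b in zip(tr.states, tr.states[1:]):
                brute[(a, b)] += 1
        assert got == dict(brute)
        # exactly one record per sojourn: censored + event = sojourn count
        n_sojourns = sum(
            sum(1 for s in tr.states if s in (DX, "HC", "HO")) for tr in small_trajectories
        )
        assert len(sojourn_records(rec)) == n_sojourns


class TestParametricFit:
    def test_exponential_closed_form(self):
        """Events {1,2,3} all observed: rate 3/6, loglik and AIC in closed form."""
        fit = fit_survival(np.array([1.0, 2.0, 3.0]), np.ones(3, bool), "exponential")
        assert np.exp(-fit.theta[0]) == pytest.approx(0.5, rel=1e-6)
        assert fit.loglik == pytest.approx(3 * np.log(0.5) - 0.5 * 6, abs=1e-8)
        assert fit.aic == pytest.approx(12.158883, abs=1e-5)
        assert fit.bic == pytest.approx(np.log(3) - 2 * fit.loglik, abs=1e-8)

    def test_all_censored_is_inestimable(self):
        with pytest.raises(InestimableError):
            fit_survival(np.ones(5), np.zeros(5, bool), "weibull")

    def test_censoring_handled(self, rng):
        """Exponential MLE with censoring: events / total exposure."""
        t = rng.exponential(50.0, 500)
        cens = np.minimum(t, 60.0)
        event = t <= 60.0
        fit = fit_survival(cens, event, "exponential")
        assert np.exp(-fit.theta[0]) == pytest.approx(event.sum() / cens.sum(), rel=1e-6)

    @pytest.mark.parametrize("family", list(DistributionFamily), ids=lambda f: f.value)
    def test_parameter_recovery_with_covariate(self, family, rng):
        """Coefficients and shape recovered within 3 MC standard errors."""
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        beta = 0.4
        kwargs = {
            DistributionFamily.EXPONENTIAL: {},
            DistributionFamily.WEIBULL: {"scale": 0.6},
            DistributionFamily.LOGNORMAL: {"scale": 0.7},
            DistributionFamily.LOGLOGISTIC: {"scale": 0.5},
            DistributionFamily.GAMMA: {"shape": 2.0},
            DistributionFamily.GENERALIZED_GAMMA: {"scale": 0.6, "shape": 0.7},
        }[family]
        base = DistributionParams(family, np.log(60.0), **kwargs)
        t = np.array([
            sample_time(base.shifted(beta * xi), 0.0, rng) for xi in x
        ])
        fit = fit_survival(t, np.ones(n, bool), family, X=x[:, None], coef_names=("x",))
        se = np.sqrt(np.diag(fit.cov))
        truth = np.append(
            np.asarray([base.location] + (
                [np.log(base.scale)] if family.has_scale else []) + (
                [np.log(base.shape)] if family is DistributionFamily.GAMMA else
                [base.shape] if family is DistributionFamily.GENERALIZED_GAMMA else []
            )),
            beta,
        )
        assert np.all(np.abs(fit.theta - truth) < 3 * se)

    def test_weibull_matches_lifelines(self, rng):
        """Independent AFT oracle: lifelines' Weibull fitter on the same data."""
        from lifelines import WeibullAFTFitter

        n = 800
        x = (rng.random(n) < 0.4).astype(float)
        t = np.array([
            sample_time(DistributionParams("weibull", np.log(30) + 0.5 * xi, 0.7), 0.0, rng)
            for xi in x
        ])
        event = t < 80.0
        t = np.minimum(t, 80.0)
        fit = fit_survival(t, event, "weibull", X=x[:, None], coef_names=("x",))
        df = pd.DataFrame({"t": t, "e": event.astype(int), "x": x})
        ll = WeibullAFTFitter().fit(df, duration_col="t", event_col="e")
        # lifelines: lambda_ = exp(intercept + beta x); rho_ = 1/scale
        assert fit.theta[0] == pytest.approx(
            ll.params_[("lambda_", "Intercept")], abs=1e-3)
        assert fit.betas[0] == pytest.approx(ll.params_[("lambda_", "x")], abs=1e-3)
        assert np.exp(fit.theta[1]) == pytest.approx(
            1.0 / ll.params_[("rho_", "Intercept")] if False else
            np.exp(-ll.params_[("rho_", "Intercept")]), abs=1e-3)
        assert fit.loglik == pytest.approx(ll.log_likelihood_, abs=1e-4)

    def test_order_invariance(self, rng):
        t = rng.gamma(2.0, 30.0, 300)
        ev = np.ones(300, bool)
        f1 = fit_survival(t, ev, "gamma")
        perm = rng.permutation(300)
        f2 = fit_survival(t[perm], ev[perm], "gamma")
        assert np.allclose(f1.theta, f2.theta, atol=1e-6)


class TestSelectFamily:
    @staticmethod
    def _records_from_times(t):
        n = len(t)
        df = pd.DataFrame({
            "kind": "sojourn", "subject": np.arange(n), "from_state": DX,
            "to_state": MO, "entry_day": 0.0, "exit_day": t, "duration": t,
            "event": True,
        })
        return df

    def test_exponential_data_selects_exponential(self, rng):
        t = rng.exponential(50.0, 4000)
        fit = select_family(self._records_from_times(t), (DX, MO), covariates=())
        assert fit.family is DistributionFamily.EXPONENTIAL
        assert len(fit.comparison) == 6

    def test_lognormal_data_selects_lognormal(self, rng):
        t = np.exp(rng.normal(np.log(60.0), 0.6, 5000))
        fit = select_family(self._records_from_times(t), (DX, MO), covariates=())
        assert fit.family in (
            DistributionFamily.LOGNORMAL, DistributionFamily.GENERALIZED_GAMMA,
        )

    def test_comparison_table_recomputable(self, rng):
        t = rng.weibull(1.5, 1000) * 40.0
        fit = select_family(self._records_from_times(t), (DX, MO), covariates=())
        tab = fit.comparison
        assert np.allclose(tab["aic"], 2 * tab["k"] - 2 * tab["loglik"])
        assert np.allclose(tab["bic"], tab["k"] * np.log(tab["n"]) - 2 * tab["loglik"])


class TestMultinomial:
    @staticmethod
    def _ed_frame(dests, origin=EDC, extra=None):
        n = len(dests)
        base = {
            "kind": "ed", "subject": np.arange(n), "from_state": origin,
            "to_state": dests, "entry_day": 10.0, "exit_day": 10.0,
            "duration": 0.0, "event": True, "age_entry": 64.0,
            "n_copd_ed": 0, "n_other_ed": 0, "n_copd_hosp": 0, "n_other_hosp": 0,
            "female": 0, "smoking": "never", "rurality": "urban", "deprivation": 1,
            **{c: 0 for c in cs.covariates.COMORBIDITIES},
        }
        df = pd.DataFrame(base)
        if extra is not None:
            for k, v in extra.items():
                df[k] = v
        return df

    def test_intercept_only_recovers_proportions(self):
        dests = [DX] * 60 + [HC] * 30 + [MO] * 10
        fit = fit_multinomial(self._ed_frame(dests), EDC, covariates=())
        probs = predict_destination_probs(fit, np.zeros(len(COEFFICIENT_NAMES)))
        assert probs[DX] == pytest.approx(0.6, abs=1e-4)
        assert probs[HC] == pytest.approx(0.3, abs=1e-4)
        assert probs[MO] == pytest.approx(0.1, abs=1e-4)

    def test_two_destination_logistic_oracle(self, rng):
        """Binary case reproduces an independent logistic regression."""
        from sklearn.linear_model import LogisticRegression

        n = 600
        female = (rng.random(n) < 0.5).astype(int)
        p = 1.0 / (1.0 + np.exp(-(-0.5 + 1.0 * female)))
        dests = np.where(rng.random(n) < p, HC, DX)
        with pytest.warns(UserWarning, match="dropped"):
            fit = fit_multinomial(
                self._ed_frame(list(dests), extra={"female": female}),
                EDC, covariates=("female",),
            )
        lr = LogisticRegression(C=np.inf, tol=1e-8, max_iter=1000).fit(
            female[:, None], (dests == HC).astype(int))
        assert fit.coefs.loc["intercept", HC] == pytest.approx(lr.intercept_[0], abs=1e-4)
        assert fit.coefs.loc["female", HC] == pytest.approx(lr.coef_[0, 0], abs=1e-4)

    def test_probabilities_sum_to_one(self, rng):
        dests = [DX] * 40 + [HC] * 25 + ["HO"] * 20 + [MO] * 15
        ages = rng.normal(64.0, 10.0, len(dests))
        fit = fit_multinomial(
            self._ed_frame(dests, extra={"age_entry": ages}), EDC,
            covariates=("age",),
        )
        x = np.zeros(len(COEFFICIENT_NAMES))
        x[0] = 11.0  # age 75
        probs = predict_destination_probs(fit, x)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= v <= 1 for v in probs.values())

    def test_reference_has_zero_log_odds(self):
        dests = [DX] * 50 + [HC] * 50
        with pytest.warns(UserWarning):
            fit = fit_multinomial(self._ed_frame(dests), EDC, covariates=())
        lp = fit.linear_predictors(np.zeros(len(COEFFICIENT_NAMES)))
        assert lp[0] == 0.0
        assert fit.destinations[0] == DX


class TestParameterTables:
    def test_round_trip(self, tmp_path, true_model):
        write_parameter_tables(true_model.parametric, true_model.multinomial, tmp_path)
        parametric, multinomial = read_parameter_tables(tmp_path)
        for arc, fit in true_model.parametric.items():
            got = parametric[arc]
            assert got.family is fit.family
            assert np.allclose(got.theta, fit.theta)
            assert np.allclose(got.cov, fit.cov)
            assert got.coef_names == fit.coef_names
        for origin, fit in true_model.multinomial.items():
            got = multinomial[origin]
            assert got.destinations == fit.destinations
            assert np.allclose(got.coefs.to_numpy(), fit.coefs.to_numpy())
            assert np.allclose(got.cov, fit.cov)
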