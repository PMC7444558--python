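"""Stratified / counterfactual orchestration, validation, CLI round trips."""

import numpy as np
import pandas as pd
import pytest

import copdsim as cs
from copdsim.outcomes import ConfidenceBand
from copdsim.scenarios import (
    ScenarioConfig,
    default_grid,
    internal_validation,
    run_counterfactual,
    run_stratified,
    write_manifest,
)


CFG = dict(horizon=8 * 365.25, n_outer=4, grid_step=91.0)


@pytest.fixture(scope="module")
def tiny_cohort():
    return cs.generate_baseline(seed=41, n=120)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="kind"):
            ScenarioConfig(kind="magic", variable="smoking")
        with pytest.raises(ValueError, match="unknown predictor"):
            ScenarioConfig(kind="stratified", variable="bmi")
        with pytest.raises(ValueError, match="forced value"):
            ScenarioConfig(kind="counterfactual", variable="smoking")

    def test_yaml_and_manifest(self, tmp_path):
        (tmp_path / "s.yaml").write_text(
            "kind: counterfactual\nvariable: smoking\nvalue: former\n"
            "n_outer: 3\nseed: 9\n"
        )
        cfg = ScenarioConfig.from_yaml(tmp_path / "s.yaml")
        assert cfg.value == "former" and cfg.n_outer == 3
        write_manifest(tmp_path / "m.json", cfg, ["a warning"])
        import json

        m = json.loads((tmp_path / "m.json").read_text())
        assert m["seed"] == 9 and m["config_digest"] == cfg.digest()
        assert m["warnings"] == ["a warning"]


class TestStratified:
    def test_smoking_strata(self, tiny_cohort, true_model):
        cfg = ScenarioConfig(kind="stratified", variable="smoking", seed=2, **CFG)
        res = run_stratified(tiny_cohort, true_model, cfg)
        assert set(res) == {"current", "former", "never"}
        assert sum(r.n_subjects for r in res.values()) == len(tiny_cohort)
        for r in res.values():
            assert set(r.bands) == {"survival", *cs.EVENT_TYPES}
            b = r.bands["survival"]
            assert np.all(b.lower <= b.upper)

    def test_single_level_equals_unstratified(self, tiny_cohort, true_model):
        uniform = tiny_cohort.copy()
        uniform["rurality"] = "urban"
        cfg = ScenarioConfig(kind="stratified", variable="rurality", seed=3, **CFG)
        res = run_stratified(uniform, true_model, cfg)
        assert list(res) == ["urban"]
        reps = cs.run_nested_uncertainty(
            uniform, true_model, horizon=cfg.horizon,
            n_outer=cfg.n_outer, seed=cfg.seed,
        )
        grid = default_grid(cfg.horizon, cfg.grid_step)
        direct = np.vstack([cs.survival_curve(r, grid) for r in reps])
        assert np.allclose(res["urban"].replicates[0]["survival"], direct)

    def test_empty_stratum_warned_and_omitted(self, tiny_cohort, true_model):
        cfg = ScenarioConfig(
            kind="stratified", variable="smoking", seed=2,
            levels=("never", "pipe"), **CFG,
        )
        sub = tiny_cohort[tiny_cohort.smoking == "never"]
        with pytest.warns(UserWarning, match="empty"):
            res = run_stratified(sub, true_model, cfg)
        assert list(res) == ["never"]


class TestCounterfactual:
    def test_null_modification_zero_contrast(self, tiny_cohort, true_model):
        """Forcing the factual value yields exactly zero under CRN."""
        quitters = tiny_cohort.copy()
        quitters["smoking"] = "former"
        cfg = ScenarioConfig(
            kind="counterfactual", variable="smoking", value="former", seed=5, **CFG
        )
        res = run_counterfactual(quitters, true_model, cfg)
        for band in res.contrasts["absolute"].values():
            assert np.all(band.mean == 0.0)
            assert np.all(band.lower == 0.0) and np.all(band.upper == 0.0)

    def test_label_swap_negates_absolute_contrasts(self, tiny_cohort, true_model):
        smokers = tiny_cohort.copy()
        smokers["smoking"] = "current"
        quit_cfg = ScenarioConfig(
            kind="counterfactual", variable="smoking", value="former", seed=6, **CFG
        )
        res_a = run_counterfactual(smokers, true_model, quit_cfg)
        former = smokers.copy()
        former["smoking"] = "former"
        back_cfg = ScenarioConfig(
            kind="counterfactual", variable="smoking", value="current", seed=6, **CFG
        )
        res_b = run_counterfactual(former, true_model, back_cfg)
        for key in res_a.contrasts["absolute"]:
            a = res_a.contrasts["absolute"][key]
            b = res_b.contrasts["absolute"][key]
            assert np.allclose(a.mean, -b.mean, atol=1e-12)

    def test_quitting_direction_of_effect(self, tiny_cohort, true_model):
        """Under the synthetic model's harmful smoking coefficients, quitters
        see fewer COPD ED visits/hospitalizations and better survival."""
        smokers = tiny_cohort.copy()
        smokers["smoking"] = "current"
        cfg = ScenarioConfig(
            kind="counterfactual", variable="smoking", value="former",
            seed=7, horizon=14 * 365.25, n_outer=4, grid_step=182.0,
        )
        res = run_counterfactual(smokers, true_model, cfg)
        # factual (non-quitters) minus modified (quitters), at the horizon
        assert res.contrasts["absolute"]["copd_ed"].mean[-1] > 0
        assert res.contrasts["absolute"]["copd_hosp"].mean[-1] > 0
        assert res.contrasts["absolute"]["survival"].mean[-1] < 0

    def test_unknown_level_rejected(self, tiny_cohort, true_model):
        cfg = ScenarioConfig(
            kind="counterfactual", variable="smoking", value="vaping", seed=5, **CFG
        )
        with pytest.raises(ValueError, match="smoking"):
            run_counterfactual(tiny_cohort, true_model, cfg)

    def test_end_to_end_determinism(self, tiny_cohort, true_model):
        cfg = ScenarioConfig(
            kind="counterfactual", variable="smoking", value="never", seed=8, **CFG
        )
        r1 = run_counterfactual(tiny_cohort.head(40), true_model, cfg)
        r2 = run_counterfactual(tiny_cohort.head(40), true_model, cfg)
        for key in r1.factual.bands:
            assert np.array_equal(r1.factual.bands[key].mean, r2.factual.bands[key].mean)
            assert np.array_equal(
                r1.contrasts["relative"][key].upper,
                r2.contrasts["relative"][key].upper,
                equal_nan=True,
            )

    def test_crn_reduces_contrast_variance(self, tiny_cohort, true_model):
        """Common random numbers shrink between-replicate contrast noise
        relative to independent streams, on a paired toy comparison."""
        smokers = tiny_cohort.head(60).copy()
        smokers["smoking"] = "current"
        quitters = smokers.copy()
        quitters["smoking"] = "former"
        grid = np.array([10 * 365.25])
        crn_diffs, indep_diffs = [], []
        for r in range(6):
            a = cs.simulate_cohort(smokers, true_model, seed=100 + r)
            b_crn = cs.simulate_cohort(quitters, true_model, seed=100 + r)
            b_ind = cs.simulate_cohort(quitters, true_model, seed=700 + r)
            sa = cs.survival_curve(a, grid)[0]
            crn_diffs.append(sa - cs.survival_curve(b_crn, grid)[0])
            indep_diffs.append(sa - cs.survival_curve(b_ind, grid)[0])
        assert np.var(crn_diffs) <= np.var(indep_diffs)


class TestInternalValidation:
    def test_self_validation_coverage(self, tiny_cohort, true_model):
        """Observed histories generated by the same model fall inside the
        simulated bands at almost every reported time point."""
        cfg_horizon, n_outer, step = 10 * 365.25, 6, 182.0
        observed = cs.generate_histories(tiny_cohort, true_model, cfg_horizon, seed=55)
        reps = cs.run_nested_uncertainty(
            tiny_cohort, true_model, horizon=cfg_horizon, n_outer=n_outer, seed=56
        )
        grid = default_grid(cfg_horizon, step)
        curves = [cs.cohort_outcomes(r, grid) for r in reps]
        bands = {
            "survival": cs.empirical_band(
                np.vstack([c.survival for c in curves]), grid),
            "copd_ed": cs.empirical_band(
                np.vstack([c.mcc["copd_ed"] for c in curves]), grid),
        }
        report = internal_validation(observed, bands)
        assert {"outcome", "observed", "simulated", "covered"} <= set(report.columns)
        assert report["covered"].mean() > 0.7
        # the horizon-row gives the long-run survival comparison
        final = report[(report.outcome == "survival")].iloc[-1]
        assert final.time_days == grid[-1]

    def test_band_edge_counts_as_covered(self):
        grid = np.array([0.0, 1.0])
        band = ConfidenceBand(
            grid, mean=np.array([0.5, 0.5]),
            lower=np.array([0.4, 0.4]), upper=np.array([0.6, 0.6]),
        )
        assert band.covers(np.array([0.4, 0.6])).all()
        assert not band.covers(np.array([0.39, 0.5])).all()


class TestCli:
    def test_pipeline_round_trip(self, tmp_path):
        """generate-cohort -> simulate-histories -> fit (reduced) -> simulate
        -> scenario, all through the CLI."""
        from click.testing import CliRunner

        from copdsim.cli import main

        runner = CliRunner()
        r = runner.invoke(main, [
            "generate-cohort", "--n", "200", "--seed", "1",
            "--out-dir", str(tmp_path),
        ])
        assert r.exit_code == 0, r.output
        cohort_file = tmp_path / "cohort.csv"
        r = runner.invoke(main, [
            "simulate-histories", "--cohort", str(cohort_file),
            "--seed", "2", "--horizon-days", "5110", "--out-dir", str(tmp_path),
        ])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, [
            "fit", "--cohort", str(cohort_file),
            "--histories", str(tmp_path / "histories.csv"),
            "--horizon-days", "5110", "--covariates", "age,smoking_current",
            "--out-dir", str(tmp_path / "fits"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "fits" / "multistate_params.tsv").exists()
        r = runner.invoke(main, [
            "simulate", "--cohort", str(cohort_file),
            "--params", str(tmp_path / "fits"),
            "--horizon-days", "2000", "--n-outer", "2", "--seed", "3",
            "--out-dir", str(tmp_path / "sim"),
        ])
        assert r.exit_code == 0, r.output
        surv = pd.read_csv(tmp_path / "sim" / "survival.csv")
        assert surv["estimate"].iloc[0] == 1.0
        (tmp_path / "cf.yaml").write_text(
            "kind: counterfactual\nvariable: smoking\nvalue: former\n"
            "n_outer: 2\nseed: 4\nhorizon: 2000\ngrid_step: 200\n"
        )
        r = runner.invoke(main, [
            "scenario", "--config", str(tmp_path / "cf.yaml"),
            "--cohort", str(cohort_file), "--out-dir", str(tmp_path / "scen"),
        ])
        assert r.exit_code == 0, r.output
        assert (tmp_path / "scen" / "manifest.json").exists()
        assert (tmp_path / "scen" / "contrast_absolute_survival.csv").exists()

    def test_mcc_command(self, tmp_path):
        from click.testing import CliRunner

        from copdsim.cli import main

        cohort = cs.generate_baseline(seed=3, n=40)
        trs = cs.generate_histories(cohort, cs.default_true_model(), 2000.0, seed=4)
        cs.states.trajectories_to_frame(trs).to_csv(tmp_path / "h.csv", index=False)
        runner = CliRunner()
        r = runner.invoke(main, [
            "mcc", "--histories", str(tmp_path / "h.csv"),
            "--horizon-days", "2000", "--out-dir", str(tmp_path),
        ])
        assert r.exit_code == 0, r.output
        out = pd.read_csv(tmp_path / "mcc_copd_ed.csv")
        assert (out["mcc"].diff().dropna() >= 0).all()
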