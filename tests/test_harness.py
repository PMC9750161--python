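"""Grid runner, EPS summaries, ANOVA effect sizes, recovery RMSE, CLI."""

import numpy as np
import pandas as pd
import pytest

from overfactor.harness import (
    SimulationCondition,
    anova_partial_eta,
    expand_grid,
    rmse_recovery,
    run_grid,
    summarize_eps,
)


@pytest.fixture(scope="module")
def tiny_results():
    grid = [SimulationCondition(N=100, p=6, r=2, loading=0.6, skew_pattern="None"),
            SimulationCondition(N=100, p=6, r=2, loading=0.6, skew_pattern="SM")]
    return run_grid(grid, methods=("fa", "pa"), replicates=4, master_seed=11,
                    pa_resamples=20)


class TestGrid:
    def test_full_grid_has_120_conditions(self):
        grid = expand_grid()
        assert len(grid) == 120
        assert len({c.condition_id for c in grid}) == 120

    def test_overrides(self):
        assert len(expand_grid(p=[6], N=[500])) == 30

    def test_linear_model_flag(self):
        assert SimulationCondition(100, 6, 1, 0.6, "SP").linear_model_true
        assert not SimulationCondition(100, 6, 1, 0.6, "MM").linear_model_true


class TestRunGrid:
    def test_row_count_and_uniqueness(self, tiny_results):
        assert len(tiny_results) == 2 * 4 * 2
        key = tiny_results[["condition_id", "replicate", "method"]]
        assert not key.duplicated().any()

    def test_determinism(self):
        grid = [SimulationCondition(N=100, p=6, r=1, loading=0.9, skew_pattern="MM")]
        a = run_grid(grid, methods=("fa",), replicates=3, master_seed=7)
        b = run_grid(grid, methods=("fa",), replicates=3, master_seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            run_grid(expand_grid(p=[6])[:1], methods=("vss",), replicates=1)


class TestSummaries:
    def test_eps_matches_independent_mean(self, tiny_results):
        out = summarize_eps(tiny_results, ["skew_pattern"])
        for _, row in out.iterrows():
            mask = (tiny_results["skew_pattern"] == row["skew_pattern"]) & (
                tiny_results["method"] == row["method"])
            expected = tiny_results.loc[mask, "retained"].dropna().astype(float).mean()
            assert row["eps"] == pytest.approx(expected)
            assert row["mc_se"] == pytest.approx(
                np.sqrt(row["eps"] * (1 - row["eps"]) / row["n_effective"]))

    def test_table3_layout_keys(self, tiny_results):
        out = summarize_eps(tiny_results, "table3")
        assert {"linear_model", "skew_pattern", "loading", "method", "eps"} <= set(out.columns)

    def test_pivot_orders_methods(self, tiny_results):
        out = summarize_eps(tiny_results, "table3", pivot=True)
        assert list(out.columns) == ["pa", "fa"]

    def test_mc_se_shrinks_with_sqrt_n(self):
        rows = []
        for n, tag in ((100, "a"), (200, "b")):
            for i in range(n):
                rows.append({"skew_pattern": tag, "p": 6, "method": "fa",
                             "retained": i % 2 == 0})
        out = summarize_eps(pd.DataFrame(rows), ["skew_pattern"])
        se = out.sort_values("skew_pattern")["mc_se"].to_numpy()
        assert se[0] / se[1] == pytest.approx(np.sqrt(2), rel=1e-9)

    def test_unknown_grouping(self, tiny_results):
        with pytest.raises(KeyError):
            summarize_eps(tiny_results, ["no_such_column"])


class TestAnova:
    def _frame(self, pvals_by_n):
        rows = []
        for N, pv in pvals_by_n.items():
            for r in (1, 2):
                for rep in range(10):
                    rows.append({"method": "fa", "N": N, "p": 6, "r": r,
                                 "loading": 0.6, "skew_pattern": "None",
                                 "p_value": pv})
        return pd.DataFrame(rows)

    def test_constant_response_zero_effects(self):
        out = anova_partial_eta(self._frame({100: 0.5, 500: 0.5}), "fa",
                                factors=("N", "r"))
        assert (out["partial_eta2"] == 0).all()

    def test_pure_main_effect_eta_one(self):
        out = anova_partial_eta(self._frame({100: 0.2, 500: 0.8}), "fa",
                                factors=("N", "r"))
        eta = dict(zip(out["term"], out["partial_eta2"]))
        assert eta["C(N)"] == pytest.approx(1.0, abs=1e-6)
        assert eta["C(r)"] == pytest.approx(0.0, abs=1e-6)

    def test_loading_by_skew_interaction_detected(self):
        """On FA p-values the loading x skew interaction carries real effect."""
        grid = expand_grid(p=[6], N=[500], r=[2])
        res = run_grid(grid, methods=("fa",), replicates=15, master_seed=21)
        out = anova_partial_eta(res, "fa", factors=("loading", "skew_pattern"))
        eta = dict(zip(out["term"], out["partial_eta2"]))
        inter = eta["C(loading):C(skew_pattern)"]
        assert inter > 0.05  # visible interaction, as in the published ANOVA


class TestRecovery:
    def _estimates(self, shift):
        rows = []
        for rep in range(3):
            rows.append({
                "condition_id": "c", "method": "fa",
                "lambda_true": [0.6] * 4, "lambda_hat": [0.6 + shift] * 4,
                "psi_hat": [1 - 0.6**2 + shift] * 4,
                "tau_true": [[0.0]] * 4, "tau_hat": [[0.0 + shift]] * 4,
            })
        return pd.DataFrame(rows)

    def test_exact_and_shifted(self):
        perfect = rmse_recovery(self._estimates(0.0))
        assert np.allclose(perfect["rmse"], 0.0, atol=1e-12)
        shifted = rmse_recovery(self._estimates(0.1))
        assert shifted["rmse"].to_numpy() == pytest.approx([0.1] * 3, abs=1e-12)

    def test_sign_alignment(self):
        df = self._estimates(0.0)
        df["lambda_hat"] = df["lambda_hat"].apply(lambda v: [-x for x in v])
        out = rmse_recovery(df)
        lam_rmse = out.loc[out["parameter_class"] == "lambda", "rmse"].iloc[0]
        assert lam_rmse == pytest.approx(0.0, abs=1e-12)

    def test_fa_attenuation_beats_wlsmv_in_mixed_skew(self):
        """FA loadings are attenuation-biased under mixed skew; WLSMV are not."""
        grid = [SimulationCondition(N=500, p=6, r=2, loading=0.9, skew_pattern="SM")]
        res, est = run_grid(grid, methods=("fa", "wlsmv"), replicates=8,
                            master_seed=3, store_estimates=True)
        out = rmse_recovery(est)
        lam = out[out["parameter_class"] == "lambda"].set_index("method")["rmse"]
        assert lam["fa"] > lam["wlsmv"]


class TestQualitativeOrdering:
    def test_method_ordering_in_mixed_skew_cell(self):
        """In the strong-mixed-skew medium-loading cell, categorical-ML is the
        worst retainer, plain FA intermediate, WLSMV/dT_M near nominal."""
        grid = [SimulationCondition(N=500, p=6, r=2, loading=0.6, skew_pattern="SM")]
        res = run_grid(grid, methods=("fa", "fac", "wlsmv", "dtm"), replicates=25,
                       master_seed=17)
        e = summarize_eps(res, []).set_index("method")["eps"]
        assert e["fac"] < e["fa"] < e["wlsmv"] + 1e-9
        assert e["wlsmv"] >= 0.8 and e["dtm"] >= 0.8


class TestCLI:
    def test_simulate_and_summarize(self, tmp_path):
        import yaml
        from click.testing import CliRunner

        from overfactor.cli import main

        cfg = tmp_path / "grid.yaml"
        cfg.write_text(yaml.safe_dump({"N": [100], "p": [6], "r": [1],
                                       "loading": [0.6], "skew_pattern": ["None"]}))
        out = tmp_path / "res.csv"
        runner = CliRunner()
        r = runner.invoke(main, ["simulate", "--config", str(cfg), "--methods", "fa",
                                 "--reps", "3", "--seed", "2", "--out", str(out)])
        assert r.exit_code == 0, r.output
        df = pd.read_csv(out)
        assert len(df) == 3
        r2 = runner.invoke(main, ["summarize", "--results", str(out), "--layout", "overall"])
        assert r2.exit_code == 0 and "fa" in r2.output
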