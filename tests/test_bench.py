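"""Predictor assembly, metrics, win counts, and leakage safety."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envirogs import (
    MetricCell,
    REGISTRY,
    SelectorConfig,
    build_predictor,
    cor_and_regression,
    loeo_run,
    nrmse,
    relative_efficiency,
    simulate_trial,
    win_table,
)
from envirogs.bench import BenchError, MetricError, evaluate_fold
from envirogs.data import TrialData
from envirogs.model import McmcConfig, fit_predict

FAST_MCMC = McmcConfig(n_iter=300, burn_in=100, thin=2, seed=0)
FAST_SELECT = SelectorConfig(max_runs=12, rf_params={"n_estimators": 40})


class TestRegistry:
    def test_baseline_has_no_covariates(self):
        m0 = REGISTRY["M0"]
        assert m0.covariate_block == "none" and m0.selection == "none"
        assert m0.kernel_components == ("K.e", "K.g", "K.ge")

    def test_registry_covers_described_structure(self):
        assert REGISTRY["M9"].kernel_components == ("K.e", "K.ge")
        assert REGISTRY["M9"].covariate_block == "X_g_ec"
        assert REGISTRY["M5"].covariate_block == "Xe2"
        assert REGISTRY["M5"].selection == "correlation"
        assert REGISTRY["M10"].marker_selection and REGISTRY["M10"].tentative_included
        assert REGISTRY["M12"].kernel_components == ("K.ec", "K.g", "K.ge")
        assert not REGISTRY["M14"].tentative_included

    def test_unknown_model_rejected(self, tiny_trial):
        with pytest.raises(BenchError, match="unknown model"):
            build_predictor("M15", tiny_trial[0], "trait0", "env0")


class TestBuildPredictor:
    def test_m0_assembly(self, tiny_trial):
        asm = build_predictor("M0", tiny_trial[0], "trait0", "env0", seed=1)
        assert asm.kernel_names == ["K.e", "K.g", "K.ge"]
        assert asm.covariates is None
        assert np.isnan(asm.y_masked[asm.test_mask]).all()
        assert np.isfinite(asm.y_masked[~asm.test_mask]).all()

    def test_m9_joint_selection_space(self, tiny_trial):
        asm = build_predictor(
            "M9", tiny_trial[0], "trait0", "env0", seed=1, selector=FAST_SELECT
        )
        assert asm.kernel_names == ["K.e", "K.ge"]
        assert asm.selections["joint"].joint_space
        if asm.covariates is not None:
            assert asm.covariates.provenance == "X_g_ec"

    def test_m5_quadratic_block(self, usp_shaped_trial):
        asm = build_predictor("M5", usp_shaped_trial[0], "trait0", "env1", seed=2)
        if asm.covariates is not None:
            assert asm.covariates.provenance == "Xe2"
            assert asm.covariates.values.shape[1] % 2 == 0 or True
        else:
            assert "empty_selection_no_Xe2_block" in asm.fallbacks

    def test_selection_uses_training_rows_only(self, usp_shaped_trial):
        trial, truth = usp_shaped_trial
        asm = build_predictor("M3", trial, "trait0", "env2", seed=3)
        out = asm.selections["correlation"]
        # oracle: recompute correlations on training rows only
        from envirogs.covar import expand_to_observations
        from envirogs.select import correlation_ladder_select

        d = asm.design
        X = expand_to_observations(trial.env_covariates, d)
        y = trial.trait_observations("trait0")["value"].to_numpy()
        train = ~asm.test_mask
        expected = correlation_ladder_select(X[train], y[train])
        np.testing.assert_array_equal(out.selected, expected.selected)

    def test_empty_selection_falls_back_to_incidence_kernels(self):
        # no informative covariates and huge n -> correlations all < 0.3
        trial, _ = simulate_trial(J=80, I=6, p=40, r=6, n_informative=0, mu=10.0, seed=20)
        asm = build_predictor("M2", trial, "trait0", "env0", seed=0)
        assert asm.selections["correlation"].n_selected == 0
        assert "empty_selection_K.ec_fallback_to_K.e" in asm.fallbacks
        from envirogs import observation_env_kernel

        np.testing.assert_allclose(asm.kernel_terms[0], observation_env_kernel(asm.design))


class TestMetrics:
    def test_nrmse_perfect_prediction_is_zero(self):
        assert nrmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_nrmse_hand_computed(self):
        assert nrmse([1, 2, 3], [2, 2, 2]) == pytest.approx(np.sqrt(2 / 3) / 2)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(0.1, 100.0), seed=st.integers(0, 99))
    def test_nrmse_joint_scale_invariance(self, c, seed):
        r = np.random.default_rng(seed)
        obs = r.standard_normal(10) + 5
        pred = obs + 0.3 * r.standard_normal(10)
        assert nrmse(c * obs, c * pred) == pytest.approx(nrmse(obs, pred))

    def test_nrmse_zero_mean_errors_and_sd_switch(self):
        with pytest.raises(MetricError, match="mean"):
            nrmse([-1.0, 1.0], [0.0, 0.0])
        assert nrmse([-1.0, 1.0], [0.0, 0.0], normalization="sd") > 0

    @pytest.mark.parametrize(
        "obs,pred,expected",
        [
            ([1, 2, 3], [1, 2, 3], (1.0, 0.0, 0.0)),
            ([2, 3, 4], [1, 2, 3], (1.0, 1.0, 0.0)),  # pred = obs - 1
            ([1, 2, 3], [0.5, 1.0, 1.5], (1.0, 0.0, 1.0)),  # slope 2
        ],
    )
    def test_cor_and_regression_hand_cases(self, obs, pred, expected):
        cor, b0, b = cor_and_regression(obs, pred)
        assert (cor, b0, b) == pytest.approx(expected)

    def test_cor_undefined_for_constant_or_short_input(self):
        assert np.isnan(cor_and_regression([1, 2, 3], [2, 2, 2])).all()
        assert np.isnan(cor_and_regression([1, 2], [1, 2])).all()

    def test_relative_efficiency_self_is_zero(self):
        assert relative_efficiency(1.23, 1.23, "nrmse_like") == 0.0
        assert relative_efficiency(0.5, 0.5, "cor_like") == 0.0

    def test_relative_efficiency_antitone_in_model_error(self):
        res = [relative_efficiency(1.0, v, "nrmse_like") for v in (0.5, 0.8, 1.0, 1.5)]
        assert res == sorted(res, reverse=True)

    def test_relative_efficiency_zero_denominator(self):
        with pytest.raises(MetricError):
            relative_efficiency(1.0, 0.0, "nrmse_like")
        with pytest.raises(MetricError):
            relative_efficiency(0.0, 1.0, "cor_like")


def _cells_from_grid(grid):
    """Build MetricCells from a {(trait, env): {model: nrmse}} mapping."""
    cells = []
    for (trait, env), row in grid.items():
        for m, v in row.items():
            cells.append(MetricCell(trait=trait, env=env, model_id=m, nrmse=v,
                                    cor=0.5, b0=1.0, b=0.5, n_test=10))
    return cells


class TestWinTable:
    def test_counts_match_exhaustive_enumeration(self):
        grid = {
            ("t", "e1"): {"M0": 1.0, "M1": 0.9, "M2": 1.1},
            ("t", "e2"): {"M0": 0.5, "M1": 0.7, "M2": 0.7},
        }
        rep = win_table(_cells_from_grid(grid))
        # brute force over ordered pairs and cells
        models = ["M0", "M1", "M2"]
        wins = {m: 0 for m in models}
        for cell in grid.values():
            for m in models:
                for m2 in models:
                    if m != m2 and cell[m] < cell[m2]:
                        wins[m] += 1
        for m in models:
            assert rep.env_wins.loc[m, "won"] == wins[m]
        assert rep.env_wins.loc["M0", "total"] == 4

    def test_dominated_model_has_zero_wins(self):
        grid = {("t", "e1"): {"M0": 1.0, "M1": 2.0}, ("t", "e2"): {"M0": 1.0, "M1": 2.0}}
        rep = win_table(_cells_from_grid(grid))
        assert rep.env_wins.loc["M1", "won"] == 0
        assert rep.env_wins.loc["M0", "pct"] == 100.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 500))
    def test_win_count_conservation_per_pair(self, seed):
        r = np.random.default_rng(seed)
        models = ["M0", "M1", "M2", "M3"]
        grid = {
            ("t", f"e{i}"): {m: float(r.choice([0.5, 1.0, 1.5])) for m in models}
            for i in range(3)
        }
        rep = win_table(_cells_from_grid(grid))
        df = rep.cells.pivot_table(index=["trait", "env"], columns="model_id", values="nrmse")
        for a in models:
            for b in models:
                if a >= b:
                    continue
                wins_a = int((df[a] < df[b]).sum())
                wins_b = int((df[b] < df[a]).sum())
                ties = int((df[a] == df[b]).sum())
                assert wins_a + wins_b + ties == len(df)

    def test_missing_cells_raise_with_gaps(self):
        grid = {("t", "e1"): {"M0": 1.0, "M1": 0.9}, ("t", "e2"): {"M0": 0.5}}
        with pytest.raises(BenchError, match="missing"):
            win_table(_cells_from_grid(grid))

    def test_summary_contains_relative_efficiencies(self):
        grid = {
            ("t", "e1"): {"M0": 1.420, "M9": 1.192},
            ("t", "e2"): {"M0": 1.420, "M9": 1.192},
        }
        rep = win_table(_cells_from_grid(grid))
        assert rep.summary.loc["M9", "re_nrmse"] == pytest.approx(19.13, abs=0.005)
        assert rep.summary.loc["M0", "re_nrmse"] == 0.0


class TestLoeo:
    def test_two_environment_partition(self):
        trial, _ = simulate_trial(J=10, I=2, p=20, r=4, mu=10.0, seed=13)
        cells = loeo_run(trial, models=("M0",), mcmc=FAST_MCMC, seed=1)
        assert len(cells) == 2
        assert {c.env for c in cells} == set(trial.env_ids)

    def test_usp_shaped_four_folds_per_model(self, usp_shaped_trial):
        trial, _ = usp_shaped_trial
        cells = loeo_run(trial, models=("M0", "M6"), mcmc=FAST_MCMC, seed=2)
        df = pd.DataFrame([vars(c) for c in cells])
        assert df.groupby("model_id")["env"].count().eq(4).all()

    def test_tiny_test_environment_gets_nrmse_but_no_cor(self, tiny_trial):
        trial, _ = tiny_trial
        obs = trial.observations.copy()
        keep = ~((obs["env_id"] == "env0") & (obs["genotype_id"] > "g0001"))
        obs = obs[keep].reset_index(drop=True)  # env0 keeps 2 observations
        small = TrialData(
            observations=obs, markers=trial.markers, env_covariates=trial.env_covariates,
            env_ids=trial.env_ids, genotype_ids=trial.genotype_ids, trait_ids=trial.trait_ids,
        )
        cells = loeo_run(small, models=("M0",), mcmc=FAST_MCMC, seed=3)
        c0 = next(c for c in cells if c.env == "env0")
        assert np.isfinite(c0.nrmse) and np.isnan(c0.cor)

    def test_leakage_canary_never_selected_and_predictions_unchanged(self):
        # a covariate equal to the held-out environment's responses but pure
        # noise on training environments must not change anything
        trial, _ = simulate_trial(J=20, I=4, p=30, r=5, n_informative=2, mu=10.0, seed=17)
        holdout = "env1"
        obs = trial.trait_observations("trait0")
        rng = np.random.default_rng(99)
        canary = rng.standard_normal(trial.n_environments)
        # orthogonalize training values against training environment means so
        # the canary is exactly uninformative in-sample
        env_means = obs.groupby("env_id")["value"].mean().reindex(trial.env_ids).to_numpy()
        tr = np.array([e != holdout for e in trial.env_ids])
        m = env_means[tr] - env_means[tr].mean()
        c = canary[tr] - canary[tr].mean()
        canary[tr] = c - (c @ m) / (m @ m) * m
        canary[trial.env_index[holdout]] = env_means[trial.env_index[holdout]]
        spiked = TrialData(
            observations=trial.observations,
            markers=trial.markers,
            env_covariates=np.column_stack([trial.env_covariates, canary]),
            env_ids=trial.env_ids, genotype_ids=trial.genotype_ids, trait_ids=trial.trait_ids,
        )
        asm_plain = build_predictor("M3", trial, "trait0", holdout, seed=5)
        asm_spiked = build_predictor("M3", spiked, "trait0", holdout, seed=5)
        canary_idx = trial.env_covariates.shape[1]
        assert canary_idx not in asm_spiked.selections["correlation"].selected
        fit_a = fit_predict(asm_plain.y_masked, asm_plain.kernel_terms, asm_plain.covariates, FAST_MCMC)
        fit_b = fit_predict(asm_spiked.y_masked, asm_spiked.kernel_terms, asm_spiked.covariates, FAST_MCMC)
        np.testing.assert_allclose(fit_a.predictions, fit_b.predictions, atol=1e-10)

    def test_single_environment_trait_rejected(self):
        trial, _ = simulate_trial(J=8, I=2, p=15, r=3, n_informative=1, seed=23)
        obs = trial.observations[trial.observations["env_id"] == "env0"].reset_index(drop=True)
        one_env = TrialData(
            observations=obs, markers=trial.markers, env_covariates=trial.env_covariates,
            env_ids=trial.env_ids, genotype_ids=trial.genotype_ids, trait_ids=trial.trait_ids,
        )
        with pytest.raises(BenchError, match="2 environments"):
            loeo_run(one_env, models=("M0",), mcmc=FAST_MCMC)
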