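import numpy as np
import pandas as pd
import pytest

import saiplan as sp


def make_design(rng, n=120, p=4):
    cols = {f"x{i}": rng.normal(size=n) for i in range(p)}
    return pd.DataFrame(cols, index=[f"plot_{i}" for i in range(n)])


class TestFitPresenceEnsemble:
    def test_single_informative_covariate_tops_every_run(self, rng):
        X = make_design(rng)
        y = (X["x1"] > 0.2).astype(int)  # deterministic threshold rule
        ens = sp.fit_presence_ensemble(X, y, n_runs=5, seed=1)
        assert (ens.std_importance["x1"] == 1.0).all()
        assert (ens.std_importance.drop(columns="x1") < 1.0).all().all()

    def test_no_signal_accuracy_near_majority_class_frequency(self, rng):
        X = make_design(rng)
        y = (rng.random(len(X)) < 0.4).astype(int)
        ens = sp.fit_presence_ensemble(X, y, n_runs=20, seed=2)
        majority = max(np.mean(y), 1 - np.mean(y))
        assert abs(ens.test_accuracy.mean() - majority) < 0.1

    def test_defaults_match_protocol(self, rng):
        X = make_design(rng, n=40)
        y = (X["x0"] > 0).astype(int)
        ens = sp.fit_presence_ensemble(X, y, seed=0, n_runs=2)
        assert ens.train_fraction == 0.7
        assert ens.metadata["n_trees"] == 500
        assert ens.metadata["max_features"] == "sqrt"
        import inspect

        sig = inspect.signature(sp.fit_presence_ensemble)
        assert sig.parameters["n_runs"].default == 20
        assert sig.parameters["train_fraction"].default == 0.7

    def test_standardization_max_is_one_each_run(self, rng):
        X = make_design(rng, n=60)
        y = (rng.random(60) < 0.5).astype(int)
        ens = sp.fit_presence_ensemble(X, y, n_runs=4, seed=3)
        assert ens.std_importance.max(axis=1).tolist() == [1.0] * 4
        assert (ens.std_importance > 0).all().all()
        assert ((ens.train_accuracy >= 0) & (ens.train_accuracy <= 1)).all()

    def test_fixed_seed_reproduces_everything(self, rng):
        X = make_design(rng, n=50)
        y = (X["x0"] + 0.5 * rng.normal(size=50) > 0).astype(int)
        a = sp.fit_presence_ensemble(X, y, n_runs=3, seed=9)
        b = sp.fit_presence_ensemble(X, y, n_runs=3, seed=9)
        pd.testing.assert_frame_equal(a.raw_importance, b.raw_importance)
        assert (a.test_accuracy == b.test_accuracy).all()

    def test_single_class_response_rejected(self, rng):
        X = make_design(rng, n=30)
        with pytest.raises(ValueError, match="degenerate response"):
            sp.fit_presence_ensemble(X, np.ones(30), n_runs=2, seed=0)


class TestSummarizeImportance:
    def test_always_max_variable_has_median_one_rank_one(self, rng):
        X = make_design(rng)
        y = (X["x2"] > 0).astype(int)
        summary = sp.summarize_importance(sp.fit_presence_ensemble(X, y, n_runs=5, seed=4))
        assert summary.index[0] == "x2"
        assert summary.loc["x2", "median"] == 1.0
        assert summary.loc["x2", "rank"] == 1

    def test_single_run_summary_equals_that_run(self, rng):
        X = make_design(rng, n=60)
        y = (rng.random(60) < 0.5).astype(int)
        ens = sp.fit_presence_ensemble(X, y, n_runs=1, seed=5)
        summary = sp.summarize_importance(ens)
        for v in X.columns:
            assert summary.loc[v, "median"] == pytest.approx(ens.std_importance[v].iloc[0])

    def test_exact_ties_ranked_alphabetically(self):
        ens = sp.ImportanceEnsemble(
            raw_importance=pd.DataFrame({"b": [2.0], "a": [2.0], "c": [1.0]}),
            std_importance=pd.DataFrame({"b": [1.0], "a": [1.0], "c": [0.5]}),
            train_accuracy=np.array([1.0]),
            test_accuracy=np.array([1.0]),
            train_fraction=0.7,
            seed=0,
        )
        summary = sp.summarize_importance(ens)
        assert list(summary.index) == ["a", "b", "c"]


class TestSoilCarbonGroupTest:
    def test_identical_groups_have_tukey_p_one(self, rng):
        soc = np.tile(rng.normal(50, 5, size=40), 2)
        counts = np.repeat([0, 1], 40)
        res = sp.soil_carbon_group_test(soc, counts)
        assert res.pairwise[0][2] == pytest.approx(1.0, abs=1e-9)

    def test_shifted_zero_group_detected(self, rng):
        counts = rng.integers(0, 3, size=145)
        soc = rng.normal(50, 8, size=145)
        soc[counts == 0] -= 16  # −2 SD shift for the zero-count plots
        res = sp.soil_carbon_group_test(soc, counts)
        frame = res.pairwise_frame()
        zero_pairs = frame[(frame.group_i == 0) | (frame.group_j == 0)]
        other_pairs = frame[(frame.group_i != 0) & (frame.group_j != 0)]
        assert (zero_pairs.p_adj < 0.01).all()
        assert (other_pairs.p_adj > 0.01).all()
        assert res.anova_p < 0.01

    def test_pairwise_covers_all_group_pairs(self, rng):
        counts = rng.integers(0, 4, size=80)
        res = sp.soil_carbon_group_test(rng.normal(size=80), counts)
        k = len(res.group_labels)
        assert len(res.pairwise) == k * (k - 1) // 2
        assert all(0 <= p <= 1 for _, _, p in res.pairwise)

    def test_singleton_group_merged_into_adjacent_count(self, rng, caplog):
        counts = np.array([0] * 30 + [1] * 30 + [5])  # a lone 5-count plot
        soc = rng.normal(size=61)
        with caplog.at_level("WARNING", logger="saiplan.importance"):
            res = sp.soil_carbon_group_test(soc, counts)
        assert res.group_labels == [0, 1]
        assert res.group_sizes[1] == 31

    def test_single_group_is_error(self, rng):
        with pytest.raises(ValueError, match="one threatened-count group"):
            sp.soil_carbon_group_test(rng.normal(size=10), np.zeros(10))
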