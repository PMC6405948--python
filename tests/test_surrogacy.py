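import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import saiplan as sp


class TestSAI:
    def test_perfect_surrogate_scores_one(self):
        assert sp.sai(S=30, O=30, R=20) == pytest.approx(1.0)

    def test_random_equivalent_scores_zero_in_both_variants(self):
        assert sp.sai(S=20, O=30, R=20) == 0.0
        assert sp.sai(S=20, O=30, R=20, variant="as_printed") == 0.0

    def test_worked_arithmetic_both_variants(self):
        assert sp.sai(S=25, O=30, R=20) == pytest.approx(0.5)
        assert sp.sai(S=25, O=30, R=20, variant="as_printed") == pytest.approx(1.0)

    def test_as_printed_variant_is_infinite_at_optimum(self):
        assert math.isinf(sp.sai(S=30, O=30, R=20, variant="as_printed"))

    def test_unmeasurable_when_optimum_equals_random(self):
        with pytest.warns(UserWarning, match="unmeasurable"):
            assert math.isnan(sp.sai(S=5, O=10, R=10))

    def test_optimum_below_random_rejected(self):
        with pytest.raises(ValueError):
            sp.sai(S=5, O=8, R=10)

    @given(
        st.floats(0, 30),
        st.floats(0.1, 30),
        st.floats(0, 29.9),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_range_consistent_bounded_by_one_iff_S_at_most_O(self, S, O, R):
        if R >= O:
            return
        value = sp.sai(S, O, R)
        assert (value <= 1) == (S <= O)
        if S == O:
            assert value == pytest.approx(1.0)


class TestRandomBaseline:
    def test_all_plots_is_total_representable_richness(self, tiny_occurrence):
        r = sp.random_baseline(tiny_occurrence, ["A", "B", "C"], k=3, n_random=10, seed=0)
        assert r == 3.0

    def test_single_plot_with_one_distinct_species_each(self):
        df = pd.DataFrame(np.eye(4, dtype=int), columns=list("ABCD"))
        r = sp.random_baseline(sp.OccurrenceMatrix(df), list("ABCD"), k=1, n_random=50, seed=1)
        assert r == 1.0

    def test_k_zero_gives_zero(self, tiny_occurrence):
        assert sp.random_baseline(tiny_occurrence, ["A"], k=0) == 0.0

    def test_matches_exhaustive_enumeration_within_monte_carlo_error(self, rng):
        inc = (rng.random((10, 5)) < 0.3).astype(int)
        df = pd.DataFrame(inc, columns=[f"s{j}" for j in range(5)])
        counts = [
            inc[list(combo)].any(axis=0).sum() for combo in itertools.combinations(range(10), 3)
        ]
        exact = np.mean(counts)
        sd = np.std(counts)
        est = sp.random_baseline(df, list(df.columns), k=3, n_random=1000, seed=4)
        assert abs(est - exact) <= 3 * sd / np.sqrt(1000)

    def test_k_larger_than_network_rejected(self, tiny_occurrence):
        with pytest.raises(ValueError):
            sp.random_baseline(tiny_occurrence, ["A"], k=4)


@pytest.fixture(scope="module")
def eval_setup():
    """Small landscape plus covariates holding signal, noise and the optimal score."""
    land = sp.generate_landscape(
        sp.SyntheticConfig(n_plots=60, n_species=80, n_threatened=12, n_covariates=3, seed=21)
    )
    occ = land.occurrence
    sel = sp.greedy_richness_selection(occ, land.threatened_ids)
    rng = np.random.default_rng(99)
    cov = sp.CovariateTable(
        pd.DataFrame(
            {
                "soil_carbon": land.covariates.data["soil_carbon"],
                "optimal_score": sp.importance_scores(sel),
                "noise_a": rng.normal(size=60),
                "noise_b": rng.normal(size=60),
            },
            index=occ.plot_ids,
        )
    )
    return occ, cov


def quick_config(**kw):
    base = dict(
        surrogate_variables=("soil_carbon",),
        q_values=(20, 50),
        n_models=6,
        n_random=100,
        n_trees=40,
        seed=5,
    )
    base.update(kw)
    return sp.EvaluationConfig(**base)


class TestEvaluateSurrogate:
    def test_curve_respects_structural_bounds(self, eval_setup):
        occ, cov = eval_setup
        curve = sp.evaluate_surrogate(occ, cov, quick_config())
        assert curve.R_mean <= curve.O
        assert (curve.S_values.to_numpy() <= curve.O).all()
        assert (curve.sai_values.to_numpy() <= 1.0).all()
        assert (curve.ci_low <= curve.ci_high).all()
        assert curve.site_budget == len(
            sp.greedy_richness_selection(occ, occ.threatened_ids).ordered_plots
        )

    def test_reliability_threshold_annotated(self, eval_setup):
        occ, cov = eval_setup
        curve = sp.evaluate_surrogate(occ, cov, quick_config())
        assert curve.reliability_threshold == 0.2

    def test_fixed_seed_is_fully_reproducible(self, eval_setup):
        occ, cov = eval_setup
        a = sp.evaluate_surrogate(occ, cov, quick_config())
        b = sp.evaluate_surrogate(occ, cov, quick_config())
        pd.testing.assert_frame_equal(a.sai_values, b.sai_values)

    def test_default_protocol_grid(self):
        cfg = sp.EvaluationConfig(surrogate_variables=("x",))
        assert cfg.q_values == tuple(range(5, 61, 5))
        assert cfg.n_models == 100
        assert cfg.n_random == 1000

    def test_unknown_surrogate_variable_rejected(self, eval_setup):
        occ, cov = eval_setup
        with pytest.raises(ValueError, match="not in covariate table"):
            sp.evaluate_surrogate(occ, cov, quick_config(surrogate_variables=("missing",)))

    def test_informative_beats_noise_surrogate(self, eval_setup):
        occ, cov = eval_setup
        good = sp.evaluate_surrogate(occ, cov, quick_config(surrogate_variables=("optimal_score",)))
        bad = sp.evaluate_surrogate(
            occ, cov, quick_config(surrogate_variables=("noise_a", "noise_b"))
        )
        assert good.sai_mean.mean() > bad.sai_mean.mean()


class TestCompareSurrogates:
    def test_duplicated_sets_yield_bitwise_identical_curves(self, eval_setup):
        occ, cov = eval_setup
        result = sp.compare_surrogates(
            occ,
            cov,
            {"a": ["soil_carbon"], "b": ["soil_carbon"]},
            quick_config(),
        )
        pd.testing.assert_frame_equal(
            result.curves["a"].sai_values, result.curves["b"].sai_values
        )
        assert (result.differences["mean_diff"] == 0).all()

    def test_paired_differences_reported_per_q_pair(self, eval_setup):
        occ, cov = eval_setup
        result = sp.compare_surrogates(
            occ,
            cov,
            {"soc": ["soil_carbon"], "noise": ["noise_a"], "both": ["soil_carbon", "noise_a"]},
            quick_config(),
        )
        assert len(result.differences) == 3 * 2  # 3 set pairs × 2 q values
        assert (result.differences["ci_low"] <= result.differences["ci_high"]).all()

    def test_single_set_rejected(self, eval_setup):
        occ, cov = eval_setup
        with pytest.raises(ValueError, match="at least 2"):
            sp.compare_surrogates(occ, cov, {"only": ["soil_carbon"]}, quick_config())
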