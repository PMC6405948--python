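import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.linear_model import LogisticRegression

import saiplan as sp
from saiplan.synthetic import ConfigurationError


class TestDefaultConfig:
    def test_emulated_network_scale(self):
        cfg = sp.default_config()
        assert cfg.n_plots == 145
        assert cfg.n_species == 470
        assert cfg.n_threatened == 37
        assert cfg.soc_effect > 0

    def test_constant_across_calls(self):
        assert sp.default_config() == sp.default_config()


class TestGenerateLandscape:
    def test_identical_seed_bitwise_identical_landscape(self):
        cfg = sp.SyntheticConfig(n_plots=40, n_species=50, n_threatened=8, seed=3)
        a, b = sp.generate_landscape(cfg), sp.generate_landscape(cfg)
        pd.testing.assert_frame_equal(a.occurrence.data, b.occurrence.data)
        pd.testing.assert_frame_equal(a.covariates.data, b.covariates.data)
        assert a.threatened_ids == b.threatened_ids

    def test_different_seeds_differ(self):
        a = sp.generate_landscape(sp.SyntheticConfig(n_plots=40, n_species=50, n_threatened=8, seed=3))
        b = sp.generate_landscape(sp.SyntheticConfig(n_plots=40, n_species=50, n_threatened=8, seed=4))
        assert not a.occurrence.data.equals(b.occurrence.data)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_plots": 0},
            {"n_plots": 1},
            {"n_threatened": 60, "n_species": 50},
            {"habitat_fraction": 0.0},
            {"baseline_prevalence_range": (0.5, 0.1)},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            sp.generate_landscape(sp.SyntheticConfig(**bad))

    def test_dimensions_and_threatened_count(self, small_landscape):
        occ = small_landscape.occurrence
        assert occ.n_plots == 60
        assert len(small_landscape.threatened_ids) == 12
        assert occ.threatened_mask.sum() == 12
        soc = small_landscape.covariates.data["soil_carbon"]
        assert (soc > 0).all() and np.isfinite(soc).all()

    def test_collinear_pair_present(self, small_landscape):
        cov = small_landscape.covariates.data
        dup = [c for c in cov.columns if c.endswith("_dup")]
        assert len(dup) == 1
        base = dup[0].removesuffix("_dup")
        assert abs(np.corrcoef(cov[base], cov[dup[0]])[0, 1]) > 0.95

    def test_truth_records_generating_slopes(self, small_landscape):
        slopes = small_landscape.truth["slopes"]
        assert slopes["soil_carbon"] == 2.0
        assert all(v == 0.0 for k, v in slopes.items() if k != "soil_carbon")


class TestStatisticalStructure:
    def test_null_effect_leaves_carbon_uncorrelated_with_threatened_count(self):
        rs = []
        for seed in range(50):
            cfg = sp.SyntheticConfig(
                n_plots=80, n_species=60, n_threatened=10, soc_effect=0.0, seed=seed
            )
            land = sp.generate_landscape(cfg)
            r = np.corrcoef(
                land.covariates.data["soil_carbon"], land.threatened_counts
            )[0, 1]
            rs.append(r)
        assert np.mean(np.abs(rs)) < 0.2
        assert np.abs(rs).max() < 0.45  # individual replicates stay small too

    def test_positive_effect_enriches_top_carbon_quartile(self):
        wins = 0
        for seed in range(50):
            cfg = sp.SyntheticConfig(
                n_plots=100, n_species=80, n_threatened=15, soc_effect=2.0, seed=seed
            )
            land = sp.generate_landscape(cfg)
            soc = land.covariates.data["soil_carbon"]
            counts = land.threatened_counts
            hi = counts[soc >= soc.quantile(0.75)].mean()
            lo = counts[soc <= soc.quantile(0.25)].mean()
            wins += hi > lo
        assert wins >= 48

    def test_marginal_prevalence_within_binomial_bounds_under_null(self):
        """With no covariate coupling, realized prevalence tracks the configured baseline."""
        cfg = sp.SyntheticConfig(
            n_plots=200,
            n_species=60,
            n_threatened=10,
            soc_effect=0.0,
            habitat_fraction=1.0,  # threatened baselines then apply network-wide
            seed=11,
        )
        land = sp.generate_landscape(cfg)
        prev = land.occurrence.data.mean()
        lo_t, hi_t = cfg.threatened_prevalence_range
        lo_b, hi_b = cfg.baseline_prevalence_range
        for s in land.occurrence.species_ids:
            lo, hi = (lo_t, hi_t) if s in set(land.threatened_ids) else (lo_b, hi_b)
            # 99% binomial envelope at the extreme admissible baselines
            lower = stats.binom.ppf(0.005, cfg.n_plots, lo) / cfg.n_plots
            upper = stats.binom.ppf(0.995, cfg.n_plots, hi) / cfg.n_plots
            assert lower <= prev[s] <= upper

    def test_generating_slope_sign_recovered_by_logistic_fit(self):
        cfg = sp.SyntheticConfig(seed=5)  # default scale, soc_effect = 2
        land = sp.generate_landscape(cfg)
        soc = land.covariates.data["soil_carbon"].to_numpy()
        z = ((soc - soc.mean()) / soc.std()).reshape(-1, 1)
        y = (land.threatened_counts > 0).astype(int)
        slope = LogisticRegression(C=1e6).fit(z, y).coef_[0, 0]
        assert slope > 0

    def test_zero_occurrence_species_dropped_with_warning(self, caplog):
        cfg = sp.SyntheticConfig(
            n_plots=30,
            n_species=200,
            n_threatened=5,
            baseline_prevalence_range=(0.005, 0.02),
            seed=2,
        )
        with caplog.at_level("WARNING", logger="saiplan.synthetic"):
            land = sp.generate_landscape(cfg)
        assert land.occurrence.n_species < 200
        assert any("zero plots" in r.getMessage() for r in caplog.records)
        assert len(land.threatened_ids) == 5  # threatened columns are resampled, not dropped
        assert (land.occurrence.data.sum() > 0).all()
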