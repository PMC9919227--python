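"""Trial generator: determinism, calibration, derived traits, authentication."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

import canepheno as cp
from canepheno.simulate import _lognormal_sigma, nearest_psd_correlation

from conftest import single_trait_config


class TestSimulateTrial:
    def test_seed_determinism(self, default_config, small_design):
        a = cp.simulate_trial(default_config, small_design, seed=42)
        b = cp.simulate_trial(default_config, small_design, seed=42)
        assert_frame_equal(a, b)

    def test_different_seeds_differ(self, default_config, small_design):
        a = cp.simulate_trial(default_config, small_design, seed=1)
        b = cp.simulate_trial(default_config, small_design, seed=2)
        assert not a.equals(b)

    def test_layout(self, small_trial, small_design):
        # 40 hybrids + the check parent, every env x replicate cell filled
        assert small_trial["genotype"].nunique() == 41
        assert "ROC22" in set(small_trial["genotype"])
        counts = small_trial.groupby(["environment", "replicate"]).size()
        assert (counts == 41).all()

    def test_sucrose_yield_calibration(self, default_config, full_design):
        """Genotype-mean sucrose yield matches the configured population:
        mean ~11.55 and SD ~4.06 t/ha within 10% averaged over seeds."""
        stats = []
        for seed in range(8):
            table = cp.simulate_trial(default_config, full_design, seed=500 + seed)
            sy = cp.genotype_means(table)["SY"]
            stats.append((sy.mean(), sy.std()))
        mean, sd = np.array(stats).mean(axis=0)
        assert mean == pytest.approx(11.55, rel=0.10)
        assert sd == pytest.approx(4.06, rel=0.10)

    def test_trait_mean_calibration(self, default_config, full_design):
        """Each base trait's genotype-mean average is within 3 SEs of its
        configured mean over repeated trials."""
        means = []
        for seed in range(25):
            table = cp.simulate_trial(default_config, full_design, seed=900 + seed)
            means.append(cp.genotype_means(table)[list(default_config.means)].mean())
        observed = pd.concat(means, axis=1)
        for trait, target in default_config.means.items():
            grand = observed.loc[trait].mean()
            se = observed.loc[trait].std(ddof=1) / np.sqrt(observed.shape[1])
            assert abs(grand - target) < 3 * se + 0.02 * target, trait

    def test_no_nongenetic_variance_gives_identical_replicates(self):
        config = single_trait_config(h2=1.0, env_effect_frac=0.0, block_sd_frac=0.0)
        design = cp.TrialDesign(n_genotypes=10, check_parent_id=None)
        table = cp.simulate_trial(config, design, seed=3)
        spread = table.groupby("genotype")["SN"].agg(lambda v: v.max() - v.min())
        assert (spread == 0).all()
        decomp = cp.variance_components(cp.anova_rcbd(table, "SN"))
        assert decomp.h2 == pytest.approx(1.0)

    def test_heritability_recovery_monte_carlo(self):
        """The ANOVA-EMS estimate averaged over seeds matches the generating
        h2 = 0.8 of a single-trait trial."""
        config = single_trait_config(h2=0.8)
        design = cp.TrialDesign(n_genotypes=135, check_parent_id=None)
        estimates = [
            cp.variance_components(cp.anova_rcbd(cp.simulate_trial(config, design, s), "SN")).h2
            for s in range(40)
        ]
        assert np.mean(estimates) == pytest.approx(0.80, abs=0.05)

    def test_non_psd_correlation_rejected(self):
        corr = pd.DataFrame(
            [[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]],
            index=["SN", "SD", "SW"], columns=["SN", "SD", "SW"],
        )
        with pytest.raises(ValueError, match="eigenvalue"):
            cp.SyntheticConfig(
                means={"SN": 5, "SD": 2.6, "SW": 1.7},
                sds={"SN": 1.4, "SD": 0.3, "SW": 0.4},
                h2={"SN": 0.8, "SD": 0.8, "SW": 0.8},
                genotypic_corr=corr,
            )

    @pytest.mark.parametrize("h2", [0.0, -0.2, 1.5])
    def test_bad_heritability_rejected(self, h2):
        with pytest.raises(ValueError, match="h2"):
            single_trait_config(h2=h2)

    def test_nearest_psd_projection(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(-1, 1, size=(6, 6))
        proj = nearest_psd_correlation(raw)
        assert np.allclose(proj, proj.T)
        assert np.allclose(np.diag(proj), 1.0)
        assert np.linalg.eigvalsh(proj).min() > -1e-10

    def test_lognormal_shape_matches_target_skew(self):
        # the standardized log-normal built from the solved shape parameter
        # has the requested skewness (closed-form moment identity)
        for gamma in (0.5, 1.4, 2.9):
            sigma = _lognormal_sigma(gamma)
            w = np.exp(sigma**2)
            assert (w + 2) * np.sqrt(w - 1) == pytest.approx(gamma, rel=1e-10)


class TestDeriveTraits:
    def _table(self, sn, sw, sc):
        return pd.DataFrame(
            {"genotype": ["g1"], "environment": ["e1"], "replicate": [1],
             "SN": [sn], "SW": [sw], "SC": [sc]}
        )

    def test_product_traits(self):
        out = cp.derive_traits(self._table(5.07, 1.72, 14.89))
        assert out["Y"].iloc[0] == pytest.approx(87.20, abs=0.005)
        assert out["SY"].iloc[0] == pytest.approx(87.204 * 0.1489, rel=1e-12)

    def test_sucrose_yield_from_yield(self):
        # Y = 77.25 and SC = 14.89 give SY = 11.50 t/ha
        out = cp.derive_traits(self._table(7.725, 1.0, 14.89))
        assert out["Y"].iloc[0] == pytest.approx(77.25)
        assert out["SY"].iloc[0] == pytest.approx(77.25 * 0.1489, rel=1e-12)
        assert out["SY"].iloc[0] == pytest.approx(11.50, abs=0.005)

    def test_idempotent(self, small_trial):
        once = cp.derive_traits(small_trial)
        twice = cp.derive_traits(once)
        assert_frame_equal(once, twice)

    def test_zero_stalk_weight_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cp.derive_traits(self._table(5.0, 0.0, 14.0))

    def test_missing_input_named(self):
        table = self._table(5.0, 1.7, 14.0).drop(columns=["SW"])
        with pytest.raises(ValueError, match="'SW'"):
            cp.derive_traits(table)


class TestTilleringRatios:
    @pytest.mark.parametrize(
        "counts, tr, etr",
        [
            ((100, 389, 251), 3.89, 251 / 389),
            ((50, 0, 0), 0.0, np.nan),
            ((10, 10, 10), 1.0, 1.0),
        ],
    )
    def test_ratios(self, counts, tr, etr):
        got_tr, got_etr = cp.tillering_ratios(*counts)
        assert got_tr == pytest.approx(tr)
        if np.isnan(etr):
            assert np.isnan(got_etr)
        else:
            assert got_etr == pytest.approx(etr)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cp.tillering_ratios(10, -1, 0)

    def test_zero_main_buds_rejected(self):
        with pytest.raises(ValueError):
            cp.tillering_ratios(0, 5, 2)


class TestAuthenticateHybrids:
    def test_any_band_means_real(self):
        markers = pd.DataFrame(
            {"m1": [0, 0, 1], "m2": [1, 0, 1], "m3": [0, 0, 1]},
            index=["s1", "s2", "s3"],
        )
        result = cp.authenticate_hybrids(markers)
        assert result.real == ("s1", "s3")
        assert result.false == ("s2",)
        assert result.n_real + result.n_false == 3

    def test_all_positive(self):
        markers = pd.DataFrame(np.ones((209, 3), dtype=bool))
        result = cp.authenticate_hybrids(markers)
        assert result.n_real == 209 and result.n_false == 0

    def test_missing_call_lists_seedlings(self):
        markers = pd.DataFrame({"m1": [1.0, np.nan], "m2": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            cp.authenticate_hybrids(markers)
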