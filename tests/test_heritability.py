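"""RCBD ANOVA, EMS variance components and broad-sense heritability."""

import numpy as np
import pandas as pd
import pytest

import canepheno as cp
from canepheno.heritability import VarianceDecomposition, anova_rcbd

from conftest import single_trait_config


def brute_force_anova(table, trait):
    """Independent SS computation by explicit mean subtraction."""
    y = table.set_index(["genotype", "environment", "replicate"])[trait]
    grand = y.mean()
    gm = y.groupby("genotype").mean()
    em = y.groupby("environment").mean()
    gem = y.groupby(["genotype", "environment"]).mean()
    bem = y.groupby(["environment", "replicate"]).mean()
    g = len(gm)
    n = len(em)
    r = table["replicate"].nunique()
    ss = {
        "genotype": n * r * ((gm - grand) ** 2).sum(),
        "environment": g * r * ((em - grand) ** 2).sum(),
        "block(environment)": g * sum(
            (bem[(e, k)] - em[e]) ** 2
            for e in em.index
            for k in sorted(table["replicate"].unique())
        ),
        "genotype:environment": r * sum(
            (gem[(i, j)] - gm[i] - em[j] + grand) ** 2 for i, j in gem.index
        ),
    }
    ss["total"] = ((y - grand) ** 2).sum()
    ss["error"] = ss["total"] - sum(v for k, v in ss.items() if k != "total")
    return ss


@pytest.fixture(scope="module")
def tiny_table():
    """3 genotypes x 2 environments x 2 replicates with hand-set effects."""
    rng = np.random.default_rng(123)
    rows = []
    g_eff = {"g1": -1.0, "g2": 0.0, "g3": 1.5}
    e_eff = {"e1": -0.5, "e2": 0.5}
    for g in g_eff:
        for e in e_eff:
            for k in (1, 2):
                rows.append(
                    {
                        "genotype": g, "environment": e, "replicate": k,
                        "y": 10 + g_eff[g] + e_eff[e] + 0.3 * k + rng.normal(0, 0.7),
                    }
                )
    return pd.DataFrame(rows)


class TestAnovaRcbd:
    def test_matches_brute_force_oracle(self, tiny_table):
        anova = anova_rcbd(tiny_table, "y")
        oracle = brute_force_anova(tiny_table, "y")
        for effect in ["genotype", "environment", "block(environment)",
                       "genotype:environment", "error"]:
            assert anova[effect]["ss"] == pytest.approx(oracle[effect], rel=1e-10)

    def test_matches_statsmodels_anova(self, tiny_table):
        """Cross-check against a general linear-model ANOVA."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        fit = smf.ols(
            "y ~ C(genotype) + C(environment) + C(environment):C(replicate)"
            " + C(genotype):C(environment)",
            data=tiny_table.assign(replicate=tiny_table["replicate"].astype(str)),
        ).fit()
        lm = anova_lm(fit, typ=1)
        anova = anova_rcbd(tiny_table, "y")
        assert anova["genotype"]["ss"] == pytest.approx(lm.loc["C(genotype)", "sum_sq"])
        assert anova["environment"]["ss"] == pytest.approx(lm.loc["C(environment)", "sum_sq"])
        assert anova["genotype:environment"]["ss"] == pytest.approx(
            lm.loc["C(genotype):C(environment)", "sum_sq"]
        )
        assert anova["error"]["ss"] == pytest.approx(lm.loc["Residual", "sum_sq"])

    def test_ss_partition_total(self, small_trial):
        anova = anova_rcbd(small_trial, "SY")
        y = small_trial["SY"]
        total = ((y - y.mean()) ** 2).sum()
        assert anova.table["ss"].sum() == pytest.approx(total, rel=1e-8)

    def test_null_model_f_near_one(self):
        """With no genotype/GxE effects the genotype F statistic averages
        near 1 (its exact null mean is df2/(df2-2))."""
        rng = np.random.default_rng(0)
        fs = []
        g_count = 40
        for _ in range(40):
            rows = []
            for g in range(g_count):
                for e in ("e1", "e2"):
                    for k in (1, 2, 3):
                        rows.append(
                            {"genotype": f"g{g}", "environment": e,
                             "replicate": k, "y": rng.normal()}
                        )
            anova = anova_rcbd(pd.DataFrame(rows), "y")
            fs.append(anova["genotype"]["F"])
        df2 = (g_count - 1) * (2 - 1)
        assert np.mean(fs) == pytest.approx(df2 / (df2 - 2), abs=0.15)

    def test_unbalanced_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="missing cell"):
            anova_rcbd(tiny_table.iloc[:-1], "y")

    def test_degrees_of_freedom(self, small_trial):
        anova = anova_rcbd(small_trial, "SN")
        g, n, r = anova.g, anova.n, anova.r
        df = anova.table["df"]
        assert df["genotype"] == g - 1
        assert df["environment"] == n - 1
        assert df["block(environment)"] == n * (r - 1)
        assert df["genotype:environment"] == (g - 1) * (n - 1)
        assert df["error"] == (g - 1) * n * (r - 1)
        assert df.sum() == g * n * r - 1


class TestVarianceComponents:
    def test_ems_inversion(self):
        """MS_G=54, MS_GE=12, MS_err=6 at n=2, r=3 invert to (7, 2, 6)."""
        anova = _anova_from_ms(ms_g=54.0, ms_ge=12.0, ms_err=6.0, n=2, r=3)
        decomp = cp.variance_components(anova)
        assert decomp.sigma_g2 == pytest.approx(7.0)
        assert decomp.sigma_ge2 == pytest.approx(2.0)
        assert decomp.sigma_e2 == pytest.approx(6.0)
        assert decomp.truncated == ()

    def test_truncation_flag(self):
        anova = _anova_from_ms(ms_g=5.0, ms_ge=12.0, ms_err=6.0, n=2, r=3)
        decomp = cp.variance_components(anova)
        assert decomp.sigma_g2 == 0.0
        assert "sigma_g2" in decomp.truncated

    def test_component_recovery_monte_carlo(self):
        """Mean estimates over seeds recover the generating components."""
        config = single_trait_config(h2=0.8)  # entry var 10 -> (8, 2, 6)
        design = cp.TrialDesign(n_genotypes=135, check_parent_id=None)
        comps = []
        for s in range(60):
            table = cp.simulate_trial(config, design, seed=2000 + s)
            d = cp.variance_components(cp.anova_rcbd(table, "SN"))
            comps.append((d.sigma_g2, d.sigma_ge2, d.sigma_e2))
        mean = np.array(comps).mean(axis=0)
        assert mean == pytest.approx([8.0, 2.0, 6.0], rel=0.15)


class TestHeritability:
    def test_closed_form(self):
        d = VarianceDecomposition("t", sigma_g2=8, sigma_ge2=2, sigma_e2=6, n=2, r=3)
        assert d.h2 == pytest.approx(0.80)

    def test_boundaries(self):
        zero_g = VarianceDecomposition("t", 0.0, 2.0, 6.0, n=2, r=3)
        assert zero_g.h2 == 0.0
        pure_g = VarianceDecomposition("t", 5.0, 0.0, 0.0, n=2, r=3)
        assert pure_g.h2 == 1.0
        empty = VarianceDecomposition("t", 0.0, 0.0, 0.0, n=2, r=3)
        assert np.isnan(empty.h2)

    def test_affine_invariance(self, small_trial):
        """Rescaling a trait's units leaves h2 unchanged."""
        rescaled = small_trial.copy()
        rescaled["SY"] = 3.7 * rescaled["SY"] + 0.0
        a = cp.variance_components(anova_rcbd(small_trial, "SY")).h2
        b = cp.variance_components(anova_rcbd(rescaled, "SY")).h2
        assert a == pytest.approx(b, rel=1e-10)

    def test_calibrated_population_bracket(self, default_config, full_design):
        """On study-scale simulations every trait's mean estimated h2 lies in
        [0.70, 0.90], bracketing the published 0.75-0.84 range."""
        tables = [
            cp.heritability_table(cp.simulate_trial(default_config, full_design, seed=3000 + s))
            for s in range(6)
        ]
        mean_h2 = pd.concat(t.set_index("trait")["h2"] for t in tables).groupby("trait").mean()
        assert len(mean_h2) == 11
        assert mean_h2.between(0.70, 0.90).all(), mean_h2.round(3).to_dict()


def _anova_from_ms(ms_g, ms_ge, ms_err, n, r, g=10):
    table = pd.DataFrame(
        {
            "ss": [ms_g * (g - 1), 1.0, 1.0, ms_ge * (g - 1) * (n - 1),
                   ms_err * (g - 1) * n * (r - 1)],
            "df": [g - 1, n - 1, n * (r - 1), (g - 1) * (n - 1), (g - 1) * n * (r - 1)],
        },
        index=["genotype", "environment", "block(environment)",
               "genotype:environment", "error"],
    )
    table["ms"] = table["ss"] / table["df"]
    table["F"] = np.nan
    table["p"] = np.nan
    return cp.AnovaTable(trait="t", table=table, g=g, n=n, r=r)
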