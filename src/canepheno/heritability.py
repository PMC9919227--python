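"""RCBD analysis of variance, variance components and broad-sense heritability.

The model for a genotype-by-environment trial with blocks nested within
environment is

    y_ijk = mu + G_i + E_j + B_k(j) + (GE)_ij + eps_ijk

With genotypes and G-by-E random, the expected mean squares give the
method-of-moments (EMS) component estimators

    sigma_e2  = MS_error
    sigma_ge2 = (MS_GE - MS_error) / r
    sigma_g2  = (MS_G - MS_GE) / (n r)

(negative estimates truncated at zero), and broad-sense heritability on an
entry-mean basis is

    h2 = sigma_g2 / (sigma_g2 + sigma_ge2 / n + sigma_e2 / (n r)).

The balanced closed form is computed directly from cell means; it is exact,
fast enough for Monte-Carlo use, and is cross-checked against a general
linear-model ANOVA in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import trait_columns

#: Effect order of the ANOVA table.
EFFECTS = ["genotype", "environment", "block(environment)", "genotype:environment", "error"]


@dataclass(frozen=True)
class AnovaTable:
    """Balanced RCBD ANOVA for one trait: SS, df, MS, F and p per effect."""

    trait: str
    table: pd.DataFrame  # index: EFFECTS; columns: ss, df, ms, F, p
    g: int
    n: int
    r: int

    def __getitem__(self, effect: str) -> pd.Series:
        return self.table.loc[effect]


@dataclass(frozen=True)
class VarianceDecomposition:
    """Variance components and heritability for one trait."""

    trait: str
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n: int
    r: int
    truncated: tuple[str, ...] = ()
    f_genotype: float = float("nan")
    p_genotype: float = float("nan")
    f_environment: float = float("nan")
    p_environment: float = float("nan")

    @property
    def h2(self) -> float:
        return heritability(self)


def _cube(table: pd.DataFrame, trait: str) -> tuple[np.ndarray, list, list, list]:
    """Reshape a balanced long table to a (genotype, environment, replicate) cube."""
    pivot = table.pivot_table(
        index="genotype", columns=["environment", "replicate"], values=trait, aggfunc="first"
    )
    if pivot.isna().any().any():
        missing = [
            (g, *cell) for g in pivot.index for cell in pivot.columns if pd.isna(pivot.loc[g, cell])
        ]
        raise ValueError(f"unbalanced design; missing cell(s): {missing[:10]}")
    envs = sorted(table["environment"].unique())
    reps = sorted(table["replicate"].unique())
    genos = list(pivot.index)
    cube = np.array(
        [[[pivot.loc[g, (e, k)] for k in reps] for e in envs] for g in genos], dtype=float
    )
    return cube, genos, envs, reps


def anova_rcbd(table: pd.DataFrame, trait: str) -> AnovaTable:
    """Closed-form balanced ANOVA of a multi-environment RCBD for one trait.

    Requires every genotype in every environment-replicate cell, at least two
    genotypes, environments and replicates.  Sums of squares partition the
    total exactly.  F tests use the conventional random-G/GE denominators:
    genotype over G-by-E, environment over blocks-within-environment, and
    G-by-E and blocks over the residual.
    """
    cube, genos, envs, reps = _cube(table, trait)
    g, n, r = cube.shape
    if g < 2 or n < 2 or r < 2:
        raise ValueError("need >= 2 genotypes, >= 2 environments and >= 2 replicates")

    grand = cube.mean()
    m_g = cube.mean(axis=(1, 2))
    m_e = cube.mean(axis=(0, 2))
    m_ge = cube.mean(axis=2)
    m_be = cube.mean(axis=0)  # (environment, replicate) cell means

    ss_g = n * r * ((m_g - grand) ** 2).sum()
    ss_e = g * r * ((m_e - grand) ** 2).sum()
    ss_b = g * ((m_be - m_e[:, None]) ** 2).sum()
    ss_ge = r * ((m_ge - m_g[:, None] - m_e[None, :] + grand) ** 2).sum()
    resid = cube - m_ge[:, :, None] - m_be[None, :, :] + m_e[None, :, None]
    ss_err = (resid**2).sum()

    df = {
        "genotype": g - 1,
        "environment": n - 1,
        "block(environment)": n * (r - 1),
        "genotype:environment": (g - 1) * (n - 1),
        "error": (g - 1) * n * (r - 1),
    }
    ss = {
        "genotype": ss_g,
        "environment": ss_e,
        "block(environment)": ss_b,
        "genotype:environment": ss_ge,
        "error": ss_err,
    }
    ms = {k: ss[k] / df[k] for k in ss}
    denom = {
        "genotype": "genotype:environment",
        "environment": "block(environment)",
        "block(environment)": "error",
        "genotype:environment": "error",
    }
    rows = []
    for effect in EFFECTS:
        if effect == "error":
            rows.append((ss[effect], df[effect], ms[effect], np.nan, np.nan))
            continue
        d = denom[effect]
        f = ms[effect] / ms[d]
        p = stats.f.sf(f, df[effect], df[d])
        rows.append((ss[effect], df[effect], ms[effect], f, p))
    out = pd.DataFrame(rows, index=EFFECTS, columns=["ss", "df", "ms", "F", "p"])
    return AnovaTable(trait=trait, table=out, g=g, n=n, r=r)


def variance_components(anova: AnovaTable) -> VarianceDecomposition:
    """EMS inversion of the ANOVA mean squares into variance components.

    Negative estimates are truncated at zero and recorded in ``truncated``.
    """
    n, r = anova.n, anova.r
    ms_g = anova["genotype"]["ms"]
    ms_ge = anova["genotype:environment"]["ms"]
    ms_err = anova["error"]["ms"]
    sigma_e2 = float(ms_err)
    raw_ge = (ms_ge - ms_err) / r
    raw_g = (ms_g - ms_ge) / (n * r)
    truncated = tuple(
        name for name, raw in (("sigma_ge2", raw_ge), ("sigma_g2", raw_g)) if raw < 0
    )
    return VarianceDecomposition(
        trait=anova.trait,
        sigma_g2=float(max(0.0, raw_g)),
        sigma_ge2=float(max(0.0, raw_ge)),
        sigma_e2=sigma_e2,
        n=n,
        r=r,
        truncated=truncated,
        f_genotype=float(anova["genotype"]["F"]),
        p_genotype=float(anova["genotype"]["p"]),
        f_environment=float(anova["environment"]["F"]),
        p_environment=float(anova["environment"]["p"]),
    )


def heritability(decomposition: VarianceDecomposition) -> float:
    """Broad-sense heritability on an entry-mean basis.

    h2 = sigma_g2 / (sigma_g2 + sigma_ge2/n + sigma_e2/(n r)); NaN when all
    components are zero (no variance to apportion).
    """
    d = decomposition
    denom = d.sigma_g2 + d.sigma_ge2 / d.n + d.sigma_e2 / (d.n * d.r)
    if denom == 0.0:
        return float("nan")
    return d.sigma_g2 / denom


def heritability_table(table: pd.DataFrame) -> pd.DataFrame:
    """Variance components and h2 for every trait in a plot-level table."""
    rows = []
    for trait in trait_columns(table):
        decomp = variance_components(anova_rcbd(table, trait))
        rows.append(
            {
                "trait": trait,
                "sigma_g2": decomp.sigma_g2,
                "sigma_ge2": decomp.sigma_ge2,
                "sigma_e2": decomp.sigma_e2,
                "h2": decomp.h2,
                "F_genotype": decomp.f_genotype,
                "p_genotype": decomp.p_genotype,
                "F_environment": decomp.f_environment,
                "p_environment": decomp.p_environment,
                "truncated": ";".join(decomp.truncated),
            }
        )
    return pd.DataFrame(rows)
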