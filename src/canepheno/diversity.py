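"""Descriptive statistics, sigma-binned Shannon-Wiener diversity and
membership-function standardization of genotype-mean traits.

The diversity index follows the germplasm-evaluation convention: each trait's
genotype means are cut into ten classes — an open lower tail below
``mean - 2*sd``, eight half-sigma classes, and an open upper tail from
``mean + 2*sd`` — and the Shannon-Wiener entropy of the class frequencies is
reported.  Entropy uses the base-2 logarithm by default: for ten classes the
natural-log entropy is capped at ln(10) = 2.303, below the 2.64–2.98 range
this index is expected to reach for near-normal traits, while the base-2
entropy of a sigma-binned normal is ~3.01.  A ``base`` argument exposes the
natural log for strict formula fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import genotype_means, trait_columns

N_CLASSES = 10


@dataclass(frozen=True)
class TraitSummary:
    """Descriptive and diversity statistics of one trait's genotype means."""

    trait: str
    n: int
    mean: float
    sd: float
    min: float
    max: float
    cv: float
    skewness: float
    kurtosis: float
    shannon: float | None = None
    class_counts: tuple[int, ...] | None = None


def describe(values: pd.Series | np.ndarray, trait: str = "") -> TraitSummary:
    """Descriptive statistics of a numeric series.

    Sample SD (divisor m-1), CV = sd/mean, moment skewness g1 and excess
    kurtosis g2.  A constant series yields zero SD/CV with skewness and
    kurtosis flagged as NaN; a zero mean flags the CV as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("at least 3 values are required for descriptive statistics")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        skew = kurt = float("nan")
        cv = 0.0 if mean != 0 else float("nan")
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=True, bias=True))
        cv = sd / mean if mean != 0 else float("nan")
    return TraitSummary(
        trait=trait, n=x.size, mean=mean, sd=sd,
        min=float(x.min()), max=float(x.max()),
        cv=cv, skewness=skew, kurtosis=kurt,
    )


def sigma_bins(values: pd.Series | np.ndarray) -> np.ndarray:
    """Count genotype means in the ten half-sigma diversity classes.

    Class 1 is (-inf, mean - 2 sd); classes 2..9 are half-open intervals
    [lower, upper) of width sd/2; class 10 is [mean + 2 sd, inf).  Boundary
    values fall in the upper class.  The binning mean and SD are those of the
    sample itself, making the counts invariant to affine transforms.
    """
    x = np.asarray(values, dtype=float)
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        raise ValueError("sigma binning is undefined for a constant sample (sd = 0)")
    edges = mean + sd * np.arange(-2.0, 2.01, 0.5)
    counts = np.bincount(np.digitize(x, edges), minlength=N_CLASSES)
    assert counts.sum() == x.size
    return counts


def shannon_index(class_counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon-Wiener diversity index H' = -sum(P_i log P_i) of class counts.

    ``base`` selects the logarithm (2 by default; use ``math.e`` for the
    natural-log form).  Empty classes contribute nothing.
    """
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("at least one class must be occupied")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / math.log(base))).sum())


def trait_summary(values: pd.Series | np.ndarray, trait: str = "", base: float = 2.0) -> TraitSummary:
    """Full per-trait summary: descriptive statistics plus sigma-binned H'."""
    summary = describe(values, trait)
    counts = sigma_bins(values)
    return TraitSummary(
        **{**summary.__dict__, "shannon": shannon_index(counts, base=base),
           "class_counts": tuple(int(c) for c in counts)},
    )


def summarize_table(
    table: pd.DataFrame, pooled: bool = True, base: float = 2.0
) -> pd.DataFrame:
    """Per-trait summary of a plot-level table at the genotype-mean level.

    Genotype means are pooled across environments by default (``pooled=False``
    summarizes each environment separately).  Returns one row per trait with
    range, mean, SD, CV, skewness, excess kurtosis and Shannon-Wiener H'.
    """
    if pooled:
        means = genotype_means(table)
        frames = {"pooled": means}
    else:
        per_env = genotype_means(table, per_environment=True)
        frames = {env: sub.droplevel("environment") for env, sub in per_env.groupby("environment")}
    rows = []
    for env, means in frames.items():
        for trait in means.columns:
            s = trait_summary(means[trait], trait, base=base)
            row = {
                "trait": trait, "n": s.n, "min": s.min, "max": s.max,
                "mean": s.mean, "sd": s.sd, "cv": s.cv,
                "skewness": s.skewness, "kurtosis": s.kurtosis, "shannon": s.shannon,
            }
            if not pooled:
                row = {"environment": env, **row}
            rows.append(row)
    return pd.DataFrame(rows)


def membership_standardize(means: pd.DataFrame) -> pd.DataFrame:
    """Fuzzy-membership (min-max) standardization of a genotype-mean matrix.

    Each trait column is mapped linearly so its minimizing genotype scores 0
    and its maximizing genotype scores 1.  Constant columns are rejected.
    """
    cols = trait_columns(means)
    lo = means[cols].min()
    hi = means[cols].max()
    constant = [c for c in cols if hi[c] == lo[c]]
    if constant:
        raise ValueError(f"cannot standardize constant trait column(s): {constant}")
    return (means[cols] - lo) / (hi - lo)
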