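"""Pearson correlation screening with significance tiers, and Ward
hierarchical clustering of standardized genotype means."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io import trait_columns

#: Significance tiers: p < threshold maps to the label, checked in order.
TIER_THRESHOLDS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson correlations of a genotype-mean trait matrix."""

    r: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        k = self.r.shape[0]
        return k * (k - 1) // 2

    def pair_counts(self) -> dict[str, int]:
        """Counts of significant / positive / negative significant pairs."""
        iu = np.triu_indices(self.r.shape[0], k=1)
        tiers = self.tier.to_numpy()[iu]
        rs = self.r.to_numpy()[iu]
        sig = tiers != "ns"
        return {
            "significant": int(sig.sum()),
            "positive_significant": int((sig & (rs > 0)).sum()),
            "negative_significant": int((sig & (rs < 0)).sum()),
            **{label: int((tiers == label).sum()) for _, label in TIER_THRESHOLDS},
            "ns": int((tiers == "ns").sum()),
        }

    def long_format(self) -> pd.DataFrame:
        """One row per unordered trait pair: trait_a, trait_b, r, p, tier."""
        cols = list(self.r.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    {"trait_a": a, "trait_b": b, "r": self.r.loc[a, b],
                     "p": self.p.loc[a, b], "tier": self.tier.loc[a, b]}
                )
        return pd.DataFrame(rows)


def _tier(p: float) -> str:
    for threshold, label in TIER_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


def correlate(means: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation matrix with t-based two-sided p values and tiers.

    Operates on a genotype-mean matrix (rows: genotypes, columns: traits).
    p values use the exact t transform with m - 2 degrees of freedom; the
    diagonal carries r = 1, p = 0.  Constant columns are rejected.
    """
    cols = trait_columns(means)
    m = len(means)
    if m < 4:
        raise ValueError("at least 4 genotypes are required for correlation screening")
    constant = [c for c in cols if means[c].nunique() <= 1]
    if constant:
        raise ValueError(f"correlations undefined for constant trait column(s): {constant}")
    r = means[cols].corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((m - 2) / np.clip(1.0 - rv**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=m - 2)
    np.fill_diagonal(p, 0.0)
    p_df = pd.DataFrame(p, index=r.index, columns=r.columns)
    tier = p_df.map(_tier)
    tier.values[np.diag_indices(len(cols))] = ""
    return CorrelationResult(r=pd.DataFrame(rv, index=r.index, columns=r.columns), p=p_df, tier=tier)


@dataclass(frozen=True)
class ClusterResult:
    """Ward agglomeration of genotypes: merge tree and k-group assignment."""

    linkage: np.ndarray  # scipy linkage matrix (m-1, 4)
    labels: pd.Series  # genotype -> group id (1..k)
    k: int

    @property
    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def ward_cluster(matrix: pd.DataFrame, k: int = 3) -> ClusterResult:
    """Ward minimum-variance clustering of genotypes, cut into ``k`` groups.

    ``matrix`` holds one row per genotype (typically membership-standardized
    trait values; z-scores work equally).  Merges follow Ward's criterion on
    Euclidean distances, so merge heights are non-decreasing.  Group ids are
    relabelled 1..k in order of first appearance in the input for
    determinism.
    """
    m = len(matrix)
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="ward")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # Deterministic relabelling: group 1 is the group of the first genotype.
    order: dict[int, int] = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
    labels = pd.Series([order[lab] for lab in raw], index=matrix.index, name="group")
    return ClusterResult(linkage=z, labels=labels, k=int(labels.max()))


def group_profile(labels: pd.Series, means: pd.DataFrame) -> pd.DataFrame:
    """Per-group trait means with each group's rank per trait.

    Ranks are 1 = highest group mean, supporting the usual narrative of
    which group carries the tall/heavy, many-stalked/sweet or high-tillering
    genotypes.  Returns a multi-indexed frame: (group, statistic) x trait.
    """
    if labels.isna().any():
        raise ValueError("every genotype needs a group label")
    grouped = means.loc[labels.index].groupby(labels)
    sizes = grouped.size()
    if (sizes == 0).any():
        raise ValueError("empty group in partition")
    gm = grouped.mean()
    ranks = gm.rank(ascending=False, axis=0).astype(int)
    gm.index = pd.MultiIndex.from_product([gm.index, ["mean"]], names=["group", "stat"])
    ranks.index = pd.MultiIndex.from_product([sizes.index, ["rank"]], names=["group", "stat"])
    return pd.concat([gm, ranks]).sort_index()
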