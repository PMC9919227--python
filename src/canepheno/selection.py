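"""Correlation-matrix PCA, Kaiser retention, comprehensive score F and elite
selection against a check parent.

The comprehensive score combines the retained principal-component scores of
each genotype with weights proportional to the components' variance
proportions,

    F = sum_k (p_k / sum_k p_k) * F_k,

and a hybrid is selected when its F strictly exceeds the check parent's.
The weights are the *unrounded* normalized proportions: rounding them to two
decimals before combining shifts F by several tenths and breaks agreement
with published selection tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import trait_columns


@dataclass(frozen=True)
class PCAModel:
    """Eigenstructure and per-genotype scores of a correlation-matrix PCA."""

    eigenvalues: np.ndarray
    proportions: np.ndarray  # percent of total variance per PC
    loadings: pd.DataFrame  # trait x PC, orthonormal columns
    scores: pd.DataFrame  # genotype x PC
    score_scale: str  # "raw" or "standardized"

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.proportions)


def fit_pca(
    means: pd.DataFrame,
    score_scale: str = "standardized",
    orient_trait: str = "SY",
) -> PCAModel:
    """PCA of the sample correlation matrix of a genotype-mean trait matrix.

    The population and the check parent enter the fit together.  Eigenvalues
    are sorted descending and sum to the number of traits.  Each loading
    vector is oriented so its ``orient_trait`` entry (or, if that entry is
    zero or the trait absent, its largest-magnitude entry) is positive,
    which pins an otherwise arbitrary sign.

    ``score_scale`` controls what the loadings are applied to: standardized
    values (``"standardized"``, the conventional choice for new analyses) or
    raw trait values (``"raw"``, which reproduces the magnitude regime of
    published selection tables built on raw-scale scores).
    """
    cols = trait_columns(means)
    if len(means) < 3:
        raise ValueError("at least 3 samples are required to fit a PCA")
    constant = [c for c in cols if means[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    if score_scale not in ("raw", "standardized"):
        raise ValueError("score_scale must be 'raw' or 'standardized'")
    x = means[cols].to_numpy(dtype=float)
    corr = np.corrcoef(x, rowvar=False)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]

    pivot = cols.index(orient_trait) if orient_trait in cols else None
    for j in range(v.shape[1]):
        anchor = v[pivot, j] if pivot is not None and v[pivot, j] != 0 else v[np.abs(v[:, j]).argmax(), j]
        if anchor < 0:
            v[:, j] = -v[:, j]

    loadings = pd.DataFrame(v, index=cols, columns=[f"PC{j + 1}" for j in range(len(cols))])
    basis = x if score_scale == "raw" else (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    scores = pd.DataFrame(basis @ v, index=means.index, columns=loadings.columns)
    return PCAModel(
        eigenvalues=w,
        proportions=100.0 * w / w.sum(),
        loadings=loadings,
        scores=scores,
        score_scale=score_scale,
    )


def kaiser_retain(model: PCAModel) -> list[int]:
    """Indices (0-based, in order) of components with eigenvalue > 1."""
    return [int(i) for i in np.flatnonzero(model.eigenvalues > 1.0)]


def composite_score(scores: pd.DataFrame, proportions: Sequence[float]) -> pd.Series:
    """Variance-proportion-weighted comprehensive value F per genotype.

    ``scores`` holds the retained PC scores (one column per retained PC) and
    ``proportions`` the matching variance proportions; the weights are the
    proportions normalized to sum to one, so any common rescaling of the
    proportions leaves F unchanged.
    """
    props = np.asarray(proportions, dtype=float)
    if props.ndim != 1 or len(props) != scores.shape[1]:
        raise ValueError(
            f"need one proportion per retained PC: got {len(props)} for {scores.shape[1]} columns"
        )
    if (props <= 0).any():
        raise ValueError("variance proportions must be positive")
    weights = props / props.sum()
    return pd.Series(scores.to_numpy(dtype=float) @ weights, index=scores.index, name="F")


def select_elite(f_values: pd.Series, check_id: str) -> pd.Series:
    """Genotypes whose comprehensive F strictly exceeds the check parent's.

    Returns the selected genotypes' F values sorted descending; the check
    itself is excluded from the result.
    """
    if check_id not in f_values.index:
        raise ValueError(f"check genotype {check_id!r} not present")
    threshold = f_values.loc[check_id]
    selected = f_values.drop(index=check_id)
    return selected[selected > threshold].sort_values(ascending=False)


@dataclass(frozen=True)
class CompositeScore:
    """Selection sheet: retained scores, comprehensive F and selection flag."""

    table: pd.DataFrame  # genotype x (F1..FK, F, selected)
    check_id: str
    check_f: float
    retained: tuple[int, ...]


def pca_select(
    means: pd.DataFrame, check_id: str, score_scale: str = "standardized"
) -> CompositeScore:
    """End-to-end selection: fit PCA, retain by Kaiser, score and select."""
    model = fit_pca(means, score_scale=score_scale)
    retained = kaiser_retain(model)
    if not retained:
        raise ValueError("no principal component passes the Kaiser criterion")
    cols = [f"PC{i + 1}" for i in retained]
    f = composite_score(model.scores[cols], model.proportions[retained])
    table = model.scores[cols].copy()
    table["F"] = f
    table["selected"] = f > f.loc[check_id]
    table.loc[check_id, "selected"] = False
    return CompositeScore(
        table=table.sort_values("F", ascending=False),
        check_id=check_id,
        check_f=float(f.loc[check_id]),
        retained=tuple(retained),
    )
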