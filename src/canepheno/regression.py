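"""Sucrose-yield estimation: OLS, stepwise model selection, the published
four-trait equation, and estimated-vs-measured validation.

The model of interest predicts sucrose yield (t/ha) from traits measurable
in the field at the seedling stage.  The published equation is

    SY = 2.01*SN + 8.32*SD + 0.79*B + 3.44*SH - 47.64

(stalk number /m2, stalk diameter cm, Brix %, stalk height m).  Fitting is
done on genotype means.  Exactly collinear predictors (Brix and laboratory
sucrose content move together almost perfectly) are dropped
deterministically — the later-listed column goes — and reported as NA rows
rather than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .reference import ALTERNATIVE_EQUATION, PUBLISHED_EQUATION

logger = logging.getLogger(__name__)


@dataclass
class RegressionModel:
    """A fitted linear model for the sucrose-yield response."""

    response: str
    terms: pd.DataFrame  # index: Intercept + predictors; columns coef, se, t, p
    dropped: tuple[str, ...]
    r2: float
    r2_adj: float
    aic: float
    nobs: int
    selection_trace: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def coefficients(self) -> pd.Series:
        return self.terms["coef"]

    def predict(self, data: pd.DataFrame) -> pd.Series:
        """Estimated response for new genotype means."""
        pred = np.full(len(data), self.terms.loc["Intercept", "coef"])
        for term in self.terms.index.drop("Intercept"):
            pred = pred + self.terms.loc[term, "coef"] * data[term].to_numpy(dtype=float)
        return pd.Series(pred, index=data.index, name=f"{self.response}_estimated")

    def summary_frame(self) -> pd.DataFrame:
        """Term table with NA rows for dropped collinear predictors."""
        out = self.terms.copy()
        for term in self.dropped:
            out.loc[term] = np.nan
        return out


def _drop_collinear(x: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later-listed columns that are linear combinations of earlier ones."""
    kept: list[str] = []
    dropped: list[str] = []
    n = len(x)
    current = np.ones((n, 1))
    for col in x.columns:
        cand = np.column_stack([current, x[col].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) > current.shape[1]:
            kept.append(col)
            current = cand
        else:
            dropped.append(col)
            logger.info("dropping rank-deficient predictor %r", col)
    return x[kept], dropped


def ols_fit(response: pd.Series, predictors: pd.DataFrame) -> RegressionModel:
    """Ordinary least squares with an intercept and collinearity handling.

    Coefficient standard errors use the unbiased residual variance; t tests
    are two-sided.  Exactly collinear predictors are dropped (later-listed
    first) and surface as NA rows in :meth:`RegressionModel.summary_frame`.
    """
    x, dropped = _drop_collinear(predictors)
    if x.shape[1] == 0 and predictors.shape[1] > 0:
        raise ValueError("no predictor left after dropping rank-deficient columns")
    if len(response) <= x.shape[1] + 1:
        raise ValueError("need more observations than model terms")
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(response.to_numpy(dtype=float), design).fit()
    names = ["Intercept"] + list(x.columns)
    terms = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}, index=names
    )
    r2 = float(fit.rsquared)
    r2_adj = float(fit.rsquared_adj)
    if not np.isfinite(r2):  # constant response: no variance to explain
        r2 = r2_adj = 0.0
    return RegressionModel(
        response=str(response.name or "response"),
        terms=terms,
        dropped=tuple(dropped),
        r2=r2,
        r2_adj=r2_adj,
        aic=float(fit.aic),
        nobs=int(fit.nobs),
    )


def _criterion(response: pd.Series, x: pd.DataFrame, criterion: str) -> float:
    design = sm.add_constant(x.to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(response.to_numpy(dtype=float), design).fit()
    return float(fit.aic if criterion == "aic" else fit.bic)


def stepwise_select(
    response: pd.Series,
    candidates: pd.DataFrame,
    criterion: str = "aic",
    enter_p: float = 0.05,
    remove_p: float = 0.10,
) -> RegressionModel:
    """Bidirectional stepwise selection starting from the full model.

    ``criterion='aic'`` (default, the convention of the classical stepwise
    tools) or ``'bic'`` greedily applies the single add/drop move that most
    improves the criterion until none does.  ``criterion='pvalue'`` instead
    repeatedly removes the worst predictor with p > ``remove_p`` and admits
    excluded predictors with p < ``enter_p``.  The final model is refit with
    :func:`ols_fit`; the add/drop trace is recorded on the returned model.

    With no informative candidate the search may end at the intercept-only
    model, which is returned with a notice.
    """
    if candidates.shape[1] < 1:
        raise ValueError("at least one candidate predictor is required")
    x, dropped_pre = _drop_collinear(candidates)
    cols = list(x.columns)
    current = list(cols)
    trace: list[tuple[str, str, float]] = []

    if criterion in ("aic", "bic"):
        best = _criterion(response, x[current], criterion)
        trace.append(("start", "+".join(current) or "intercept", best))
        while True:
            moves: list[tuple[float, str, str]] = []
            for col in current:
                sub = [c for c in current if c != col]
                moves.append((_criterion(response, x[sub], criterion), "drop", col))
            for col in cols:
                if col not in current:
                    moves.append((_criterion(response, x[current + [col]], criterion), "add", col))
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], m[1], m[2]))
            value, action, col = moves[0]
            if value >= best - 1e-10:
                break
            best = value
            current = [c for c in current if c != col] if action == "drop" else current + [col]
            trace.append((action, col, value))
    elif criterion == "pvalue":
        while True:
            changed = False
            if current:
                fit = ols_fit(response, x[current])
                pvals = fit.terms["p"].drop("Intercept")
                worst = pvals.idxmax()
                if pvals[worst] > remove_p:
                    current.remove(worst)
                    trace.append(("drop", worst, float(pvals[worst])))
                    changed = True
            if not changed:
                for col in cols:
                    if col in current:
                        continue
                    fit = ols_fit(response, x[current + [col]])
                    p = float(fit.terms.loc[col, "p"])
                    if p < enter_p:
                        current.append(col)
                        trace.append(("add", col, p))
                        changed = True
                        break
            if not changed:
                break
    else:
        raise ValueError("criterion must be 'aic', 'bic' or 'pvalue'")

    if not current:
        logger.info("stepwise selection retained no predictor; returning intercept-only model")
        design = np.ones((len(response), 1))
        fit = sm.OLS(response.to_numpy(dtype=float), design).fit()
        terms = pd.DataFrame(
            {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
            index=["Intercept"],
        )
        model = RegressionModel(
            response=str(response.name or "response"),
            terms=terms,
            dropped=tuple(dropped_pre),
            r2=0.0,
            r2_adj=0.0,
            aic=float(fit.aic),
            nobs=int(fit.nobs),
        )
    else:
        # Keep the candidate-list order in the refit for stable reporting.
        model = ols_fit(response, x[[c for c in cols if c in current]])
        model.dropped = tuple(dropped_pre) + model.dropped
    model.selection_trace = trace
    return model


def published_equation(
    SN: float | np.ndarray | pd.Series,
    SD: float | np.ndarray | pd.Series,
    B: float | np.ndarray | pd.Series,
    SH: float | np.ndarray | pd.Series,
) -> float | np.ndarray | pd.Series:
    """The published four-trait sucrose-yield estimate (t/ha).

    SY = 2.01*SN + 8.32*SD + 0.79*B + 3.44*SH - 47.64.  Inputs outside the
    calibration range can produce non-physical (negative) estimates; they
    are returned as-is and flagged by a warning log.
    """
    c = PUBLISHED_EQUATION
    est = c["SN"] * SN + c["SD"] * SD + c["B"] * B + c["SH"] * SH + c["Intercept"]
    if np.any(np.asarray(est) <= 0):
        logger.warning("published_equation: non-positive estimate(s); outside calibration range")
    return est


def alternative_equation(
    SN: float | np.ndarray | pd.Series,
    B: float | np.ndarray | pd.Series,
    SW: float | np.ndarray | pd.Series,
) -> float | np.ndarray | pd.Series:
    """Alternative three-trait estimate, SY = 1.97*SN + 0.80*B + 6.38*SW - 34.03.

    Provided for completeness only: at the study population's trait means it
    evaluates far below the observed mean sucrose yield, so the four-trait
    equation should be preferred.
    """
    c = ALTERNATIVE_EQUATION
    return c["SN"] * SN + c["B"] * B + c["SW"] * SW + c["Intercept"]


@dataclass(frozen=True)
class ValidationReport:
    """Agreement between estimated and measured sucrose yields."""

    r: float
    r_p: float
    var_f: float
    var_p: float
    mean_f: float
    mean_p: float
    residuals: pd.Series
    alpha: float = 0.05

    @property
    def verdict(self) -> str:
        """'aa' when means are statistically indistinguishable, else 'ab'."""
        return "aa" if self.mean_p >= self.alpha else "ab"

    @property
    def variances_equal(self) -> bool:
        return self.var_p >= self.alpha

    @property
    def means_equal(self) -> bool:
        return self.mean_p >= self.alpha


def validate(estimated: pd.Series, measured: pd.Series, alpha: float = 0.05) -> ValidationReport:
    """Compare estimated against measured sucrose yield.

    Reports the Pearson correlation, a two-sided F test of variance
    equality, and a one-way ANOVA (equivalent to a two-sample t test for two
    groups) of mean equality at level ``alpha``.
    """
    if len(estimated) != len(measured):
        raise ValueError("estimated and measured series must have equal length")
    if len(estimated) < 3:
        raise ValueError("at least 3 paired values are required")
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    r, r_p = stats.pearsonr(est, mea)
    v1, v2 = est.var(ddof=1), mea.var(ddof=1)
    f_stat = v1 / v2
    df = len(est) - 1
    var_p = 2.0 * min(stats.f.sf(f_stat, df, df), stats.f.cdf(f_stat, df, df))
    mean_f, mean_p = stats.f_oneway(est, mea)
    residuals = pd.Series(est - mea, index=estimated.index, name="residual")
    return ValidationReport(
        r=float(r), r_p=float(r_p),
        var_f=float(f_stat), var_p=float(min(var_p, 1.0)),
        mean_f=float(mean_f), mean_p=float(mean_p),
        residuals=residuals, alpha=alpha,
    )
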