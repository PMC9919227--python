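"""Synthetic multi-environment RCBD trials for a hybrid F1 breeding population.

The generator emulates the structure of a sugarcane F1 trial: ``n_genotypes``
hybrids (plus an optional elite check parent) grown in a randomized
complete-block design with ``n_replicates`` blocks in each of several
environments (years).  Each base trait follows the classical random-effects
decomposition

    y_ijk = mu + E_j + g_i + (ge)_ij + b_jk + eps_ijk

with genotypic effects ``g`` correlated across traits through a Gaussian
copula, and the variance shares of ``g``, ``ge`` and ``eps`` chosen so that
the entry-mean broad-sense heritability

    h2 = sigma_g^2 / (sigma_g^2 + sigma_ge^2 / n + sigma_e^2 / (n r))

equals its configured target.  Sucrose content is generated as a near-affine
function of Brix, and the product traits cane yield (Y = SN * SW, scaled to
t/ha) and sucrose yield (SY = Y * SC) are appended by :func:`derive_traits`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import reference
from .io import PERCENT_TRAITS, POSITIVE_TRAITS, validate_phenotypes

logger = logging.getLogger(__name__)

_RESAMPLE_LIMIT = 1000


@dataclass(frozen=True)
class TrialDesign:
    """Layout of a multi-environment randomized complete-block trial."""

    n_genotypes: int = 135
    environments: tuple[str, ...] = ("2020", "2021")
    n_replicates: int = 3
    check_parent_id: str | None = reference.CHECK_PARENT

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if len(self.environments) == 0:
            raise ValueError("at least one environment is required")

    @property
    def n_environments(self) -> int:
        return len(self.environments)


@dataclass
class SyntheticConfig:
    """Generating parameters of the synthetic trial.

    Parameters
    ----------
    means, sds
        Per-trait generating mean and total (entry-mean) standard deviation.
    h2
        Per-trait target broad-sense heritability on an entry-mean basis,
        in (0, 1].  A value of 1 means no non-genetic variance.
    genotypic_corr
        Correlation matrix of the genotypic effects across traits
        (symmetric, unit diagonal, positive semi-definite).
    skew_targets
        Target genotype-mean skewness for traits generated with log-normal
        genotypic effects; empty dict disables skewing.
    sc_link
        ``(slope, intercept, residual_sd)`` of the affine Brix -> sucrose
        content link; ``None`` disables SC generation.
    noise_corr
        Correlation matrix applied to the G-by-E and plot-residual draws
        across traits (default ``None`` = independent noise).  A negative
        stalk-number/stalk-weight entry models within-plot competition:
        denser stands carry lighter stalks, which pulls the mean of the
        product trait cane yield below the product of the trait means
        without eroding its genotypic variance.
    env_effect_frac, block_sd_frac
        Environment main-effect spread and block-effect SD, as fractions of
        each trait's entry-mean SD.
    """

    means: dict[str, float]
    sds: dict[str, float]
    h2: dict[str, float]
    genotypic_corr: pd.DataFrame
    skew_targets: dict[str, float] = field(default_factory=dict)
    sc_link: tuple[float, float, float] | None = None
    noise_corr: pd.DataFrame | None = None
    env_effect_frac: float = 0.25
    block_sd_frac: float = 0.2

    def __post_init__(self) -> None:
        traits = list(self.means)
        for name, d in (("sds", self.sds), ("h2", self.h2)):
            if set(d) != set(traits):
                raise ValueError(f"{name} must cover exactly the configured traits {traits}")
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("all trait SDs must be positive")
        for t, h in self.h2.items():
            if not 0 < h <= 1:
                raise ValueError(f"h2 for {t!r} must lie in (0, 1], got {h}")
        corr = self.genotypic_corr.loc[traits, traits]
        if not np.allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-10):
            raise ValueError("genotypic correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr.to_numpy()), 1.0, atol=1e-10):
            raise ValueError("genotypic correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(corr.to_numpy())
        if w.min() < -1e-10:
            raise ValueError(
                f"genotypic correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.3e})"
            )
        self.genotypic_corr = corr
        if self.noise_corr is not None:
            nc = self.noise_corr.loc[traits, traits]
            wn = np.linalg.eigvalsh(nc.to_numpy())
            if wn.min() < -1e-10:
                raise ValueError(
                    f"noise correlation matrix is not positive semi-definite "
                    f"(smallest eigenvalue {wn.min():.3e})"
                )
            self.noise_corr = nc

    @property
    def traits(self) -> list[str]:
        return list(self.means)


def nearest_psd_correlation(corr: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at zero and the diagonal renormalized to one.
    """
    sym = (corr + corr.T) / 2
    w, v = np.linalg.eigh(sym)
    psd = (v * np.clip(w, 0, None)) @ v.T
    d = np.sqrt(np.diag(psd))
    return psd / np.outer(d, d)


def default_genotypic_correlation() -> pd.DataFrame:
    """Default genotypic correlation among the eight base traits.

    Signs follow the trait relationships of the study population (tillering
    ratios positively coupled; stalk diameter against stalk number but with
    stalk weight; internode length with stalk height and Brix), with moderate
    magnitudes projected to the nearest PSD correlation matrix.
    """
    traits = reference.BASE_TRAITS
    corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)

    def put(a: str, b: str, r: float) -> None:
        corr.loc[a, b] = corr.loc[b, a] = r

    put("TR", "ETR", 0.50)
    put("SN", "SD", -0.40)
    put("SD", "SW", 0.50)
    put("SN", "SW", -0.35)
    put("IL", "SH", 0.40)
    put("IL", "B", 0.30)
    put("SH", "B", 0.20)
    projected = nearest_psd_correlation(corr.to_numpy())
    return pd.DataFrame(projected, index=traits, columns=traits)


def default_noise_correlation() -> pd.DataFrame:
    """Default correlation of the non-genetic (G-by-E and residual) draws.

    Identity apart from a negative stalk-number/stalk-weight entry capturing
    within-plot competition: plots that tiller into denser stands produce
    lighter individual stalks.  This plot-level tradeoff is what keeps the
    mean of the product trait cane yield below the product of the stalk
    number and stalk weight means, as observed in real cane trials, while
    leaving the product's genotypic variance (hence heritability) intact.
    """
    traits = reference.BASE_TRAITS
    corr = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    corr.loc["SN", "SW"] = corr.loc["SW", "SN"] = -0.6
    return corr


def default_config() -> SyntheticConfig:
    """Generator configuration calibrated to the study population.

    Trait means, SDs and heritabilities come from the published per-trait
    summary; TR, ETR and Brix carry log-normal genotypic effects to match
    the published skewness; sucrose content is tied to Brix by an affine
    link whose slope matches the published SD ratio.
    """
    cal = reference.TRAIT_CALIBRATION
    base = reference.BASE_TRAITS
    slope = cal.loc["SC", "sd"] / cal.loc["B", "sd"]
    intercept = cal.loc["SC", "mean"] - slope * cal.loc["B", "mean"]
    return SyntheticConfig(
        means={t: float(cal.loc[t, "mean"]) for t in base},
        sds={t: float(cal.loc[t, "sd"]) for t in base},
        h2={t: float(cal.loc[t, "h2"]) for t in base},
        genotypic_corr=default_genotypic_correlation(),
        skew_targets={t: float(cal.loc[t, "skewness"]) for t in ("TR", "ETR", "B")},
        sc_link=(float(slope), float(intercept), 0.2),
        noise_corr=default_noise_correlation(),
    )


def variance_split(total_var: float, h2: float, n: int, r: int) -> tuple[float, float, float]:
    """Split an entry-mean variance into (sigma_g2, sigma_ge2, sigma_e2).

    ``total_var`` is the variance of genotype means pooled over ``n``
    environments and ``r`` replicates.  The genotypic share is ``h2``; the
    remainder is divided equally between the G-by-E and residual entry-mean
    contributions, so plugging the components back into the heritability
    formula returns ``h2`` exactly.
    """
    vg = h2 * total_var
    rem = total_var - vg
    vge = n * rem / 2
    ve = n * r * rem / 2
    return vg, vge, ve


def _lognormal_sigma(target_skew: float) -> float:
    """Shape parameter of a log-normal with the given skewness (Cardano)."""
    q = target_skew / 2
    s = math.sqrt(q * q + 1)
    u = math.copysign(abs(q + s) ** (1 / 3), q + s) + math.copysign(abs(q - s) ** (1 / 3), q - s)
    return math.sqrt(math.log(1 + u * u))


def _skewed_standardize(z: np.ndarray, sigma_l: float) -> np.ndarray:
    """Map standard-normal latents to a zero-mean unit-variance log-normal."""
    w = math.exp(sigma_l**2)
    return (np.exp(sigma_l * z) - math.sqrt(w)) / math.sqrt(w * (w - 1))


def simulate_trial(config: SyntheticConfig, design: TrialDesign, seed: int) -> pd.DataFrame:
    """Simulate a plot-level phenotype table for the configured trial.

    Returns a long-format table with one row per (genotype, environment,
    replicate) and the configured base traits plus, when SN, SW and Brix are
    all present, sucrose content and the derived product traits.  The check
    parent, when requested, is generated as an elite entry whose latent
    genotypic score sits at the 80th population percentile for every trait.

    Identical (config, design, seed) produce identical tables.
    """
    rng = np.random.default_rng(seed)
    traits = config.traits
    n, r = design.n_environments, design.n_replicates
    genotypes = [f"F1-{i}" for i in range(1, design.n_genotypes + 1)]
    if design.check_parent_id is not None:
        genotypes = genotypes + [design.check_parent_id]
    g_count = len(genotypes)

    # Correlated genotypic latents via a Gaussian copula; the check parent's
    # latent is pinned at the 80th percentile (an elite, stable entry).
    chol = np.linalg.cholesky(config.genotypic_corr.to_numpy() + 1e-12 * np.eye(len(traits)))
    latent = rng.standard_normal((g_count, len(traits))) @ chol.T
    if design.check_parent_id is not None:
        latent[-1, :] = norm.ppf(0.80)

    env_spread = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    n_traits = len(traits)
    if config.noise_corr is not None:
        chol_noise = np.linalg.cholesky(config.noise_corr.to_numpy() + 1e-12 * np.eye(n_traits))
    else:
        chol_noise = np.eye(n_traits)
    ge_lat = rng.standard_normal((g_count, n, n_traits)) @ chol_noise.T
    eps_lat = rng.standard_normal((g_count, n, r, n_traits)) @ chol_noise.T
    block_lat = rng.standard_normal((n, r, n_traits))

    columns: dict[str, np.ndarray] = {}
    for t_idx, trait in enumerate(traits):
        sd = config.sds[trait]
        vg, vge, ve = variance_split(sd**2, config.h2[trait], n, r)
        if trait in config.skew_targets and vg > 0:
            gamma_g = config.skew_targets[trait] / config.h2[trait] ** 1.5
            g_eff = math.sqrt(vg) * _skewed_standardize(latent[:, t_idx], _lognormal_sigma(gamma_g))
        else:
            g_eff = math.sqrt(vg) * latent[:, t_idx]
        env_eff = config.env_effect_frac * sd * env_spread
        block_eff = config.block_sd_frac * sd * block_lat[:, :, t_idx]
        ge_eff = math.sqrt(vge) * ge_lat[:, :, t_idx]
        eps = math.sqrt(ve) * eps_lat[:, :, :, t_idx]

        values = (
            config.means[trait]
            + env_eff[None, :, None]
            + g_eff[:, None, None]
            + ge_eff[:, :, None]
            + block_eff[None, :, :]
            + eps
        )
        if ve > 0:
            values = _resample_out_of_range(values, trait, rng, math.sqrt(ve), values - eps)
        columns[trait] = values.reshape(-1)

    if config.sc_link is not None and "B" in columns:
        slope, intercept, resid_sd = config.sc_link
        sc = slope * columns["B"] + intercept + rng.normal(0.0, resid_sd, size=columns["B"].shape)
        bad = (sc <= 0) | (sc >= 100)
        for _ in range(_RESAMPLE_LIMIT):
            if not bad.any():
                break
            sc[bad] = slope * columns["B"][bad] + intercept + rng.normal(0.0, resid_sd, size=bad.sum())
            bad = (sc <= 0) | (sc >= 100)
        columns["SC"] = sc

    env_ix, rep_ix = np.meshgrid(np.arange(n), np.arange(r), indexing="ij")
    table = pd.DataFrame(
        {
            "genotype": np.repeat(genotypes, n * r),
            "environment": np.tile([design.environments[j] for j in env_ix.ravel()], g_count),
            "replicate": np.tile(rep_ix.ravel() + 1, g_count),
            **columns,
        }
    )
    if {"SN", "SW", "SC"} <= set(table.columns):
        table = derive_traits(table)
    return validate_phenotypes(table)


def _resample_out_of_range(
    values: np.ndarray,
    trait: str,
    rng: np.random.Generator,
    eps_sd: float,
    base: np.ndarray,
) -> np.ndarray:
    """Redraw plot residuals that push a trait outside its support.

    Resampling (rather than truncation) avoids a point mass at the bound.
    Traits without a bound are returned unchanged.
    """
    if trait in PERCENT_TRAITS:
        invalid = lambda v: (v <= 0) | (v >= 100)  # noqa: E731
    elif trait in POSITIVE_TRAITS or trait in ("TR", "ETR"):
        invalid = lambda v: v <= 0  # noqa: E731
    else:
        return values
    bad = invalid(values)
    for _ in range(_RESAMPLE_LIMIT):
        if not bad.any():
            return values
        values = values.copy()
        values[bad] = base[bad] + rng.normal(0.0, eps_sd, size=int(bad.sum()))
        bad = invalid(values)
    raise RuntimeError(
        f"could not keep trait {trait!r} inside its support after {_RESAMPLE_LIMIT} "
        "residual redraws; the configured mean/SD are implausible for this trait"
    )


def derive_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Append the product traits cane yield and sucrose yield.

    Y [t/ha] = SN [/m2] * SW [kg] * 10 (kg/m2 -> t/ha) and
    SY [t/ha] = Y * SC [%] / 100.  Existing Y/SY columns are overwritten
    with a logged notice.  Re-deriving is idempotent.
    """
    for needed in ("SN", "SW", "SC"):
        if needed not in table.columns:
            raise ValueError(f"cannot derive product traits: input trait {needed!r} is missing")
    if (table["SN"] <= 0).any() or (table["SW"] <= 0).any():
        raise ValueError("SN and SW must be strictly positive to derive yield")
    if ((table["SC"] <= 0) | (table["SC"] >= 100)).any():
        raise ValueError("SC must lie in (0, 100) to derive sucrose yield")
    out = table.copy()
    for col in ("Y", "SY"):
        if col in out.columns:
            logger.info("derive_traits: overwriting existing column %r", col)
    out["Y"] = out["SN"] * out["SW"] * 10.0
    out["SY"] = out["Y"] * out["SC"] / 100.0
    return out


def tillering_ratios(
    main_bud_count: int, tillering_count: int, tillering_stalk_count: int
) -> tuple[float, float]:
    """Tillering ratio and effective tillering ratio from raw row counts.

    TR = tillering_count / main_bud_count;
    ETR = tillering_stalk_count / tillering_count (NaN when no tillers).
    """
    if min(main_bud_count, tillering_count, tillering_stalk_count) < 0:
        raise ValueError("counts must be non-negative")
    if main_bud_count == 0:
        raise ValueError("main bud seedling count must be positive")
    tr = tillering_count / main_bud_count
    etr = tillering_stalk_count / tillering_count if tillering_count > 0 else float("nan")
    return tr, etr


@dataclass(frozen=True)
class AuthenticationResult:
    """Partition of seedlings into real and false hybrids."""

    real: tuple[str, ...]
    false: tuple[str, ...]

    @property
    def n_real(self) -> int:
        return len(self.real)

    @property
    def n_false(self) -> int:
        return len(self.false)


def authenticate_hybrids(markers: pd.DataFrame) -> AuthenticationResult:
    """Classify seedlings as real or false hybrids from marker band calls.

    ``markers`` holds one row per seedling and one boolean column per
    male-parent-specific marker band.  A seedling is a real hybrid as soon as
    any marker shows the male parent's band; a seedling with no band on any
    marker is a false hybrid (selfing or contamination).
    """
    if markers.shape[1] < 1:
        raise ValueError("at least one marker column is required")
    missing = markers.index[markers.isna().any(axis=1)]
    if len(missing):
        raise ValueError(f"missing marker call(s) for seedling(s): {list(missing)}")
    calls = markers.astype(bool)
    is_real = calls.any(axis=1)
    return AuthenticationResult(
        real=tuple(str(i) for i in calls.index[is_real]),
        false=tuple(str(i) for i in calls.index[~is_real]),
    )
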