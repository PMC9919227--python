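# Methods

## The trial and its model

The package targets the standard multi-environment evaluation of a sugarcane
hybrid F₁ population: every genotype grown in a randomized complete-block
design (RCBD) with `r` replicates in each of `n` environments (here,
consecutive growing seasons). Eleven traits are carried throughout:
tillering ratio (TR), effective tillering ratio (ETR), stalk number
(SN, /m²), stalk diameter (SD, cm), internode length (IL, cm), stalk height
(SH, m), Brix (B, %), stalk weight (SW, kg), sucrose content (SC, %), cane
yield (Y, t/ha) and sucrose yield (SY, t/ha). Y and SY are products, not
measurements: Y = SN·SW·10 (kg/m² → t/ha) and SY = Y·SC/100.

The plot-level observation model for each trait is the classical
random-effects decomposition

    y_ijk = μ + E_j + g_i + (ge)_ij + b_k(j) + ε_ijk

with genotype i, environment j, block k nested in environment. Genotype and
G×E are treated as random; blocks are nested within environment (an RCBD is
laid out per season, so blocks are not crossed with environments).

## Variance components and heritability

`anova_rcbd` computes the balanced closed-form sums of squares from cell
means; they partition the total exactly and are cross-checked in the tests
against a general linear-model ANOVA and a brute-force mean-subtraction
oracle. F tests use the random-model denominators (genotype over G×E,
environment over blocks-within-environment, G×E and blocks over residual).

The expected-mean-squares (method-of-moments) estimators are

    σ̂²e  = MS_error
    σ̂²ge = (MS_GE − MS_error) / r
    σ̂²g  = (MS_G − MS_GE) / (n·r)

with negative estimates truncated at zero (and flagged); heritability on an
entry-mean basis is h² = σ²g / (σ²g + σ²ge/n + σ²e/(nr)), computed from the
truncated components so it stays in [0, 1]. EMS estimation (rather than
REML) is used because it is the estimator the heritability formula presumes
and is exactly testable against hand-computable mean squares on balanced
data; the package targets balanced designs and rejects unbalanced tables
with the missing cells named.

## Diversity statistics

Descriptive statistics use the sample SD (divisor m−1), CV = σ/x̄, and the
unadjusted moment coefficients g₁ (skewness) and excess g₂ (kurtosis) — the
excess convention is what makes slightly platykurtic traits print small
negative kurtosis values.

The Shannon–Wiener index H′ = −Σ Pᵢ log Pᵢ is computed over ten classes:
an open lower tail below x̄ − 2σ, eight half-σ classes, and an open upper
tail from x̄ + 2σ, with boundary values assigned to the upper class
(half-open-below intervals; deterministic). The binning mean and SD are
those of the genotype-mean sample being binned, pooled across environments,
which makes the class counts invariant to affine changes of units.

**Logarithm base.** The index uses log₂ by default. The natural-log entropy
of ten classes is capped at ln 10 ≈ 2.30, below the 2.6–3.0 range this
index reaches for near-normal breeding traits, whereas the base-2 entropy
of an exactly normal trait under this binning is 3.012 asymptotically
(≈2.97 at m = 135 after plug-in small-sample bias). A `base` argument
exposes the natural-log form for strict formula fidelity.

Membership (fuzzy min–max) standardization maps each trait column linearly
onto [0, 1] with the minimizing genotype at 0 and the maximizing one at 1;
constant columns are rejected by name.

## Correlation and clustering

Pearson correlations are computed on genotype means pooled across
environments; two-sided p values use the exact t transform with m−2 df, and
pairs are tiered at 0.05/0.01/0.001. Ward clustering operates on
membership-standardized means (z-scores work equally; the membership scale
is the convention used for this workflow's cluster heatmaps) via SciPy's
linkage; merge heights are non-decreasing by construction, and the tests
verify the merge sequence against an independently coded Lance–Williams
recurrence on small instances. Group labels are renumbered in order of
first appearance for cross-platform determinism; k = 3 is the default cut.

## PCA selection

The PCA eigendecomposes the sample correlation matrix of the 11 traits with
the check parent included in the fit (it must be scored on the same axes as
the progeny). Eigenvalues sum to the trait count; components with λ > 1 are
retained (Kaiser). Each loading vector is oriented so its sucrose-yield
entry is positive (falling back to the largest-magnitude entry), pinning
the otherwise arbitrary eigenvector sign.

Scores come in two scales. `standardized` (default) applies loadings to
z-scored traits — the conventional choice, and the one in which PC scores
are exactly uncorrelated. `raw` applies them to raw trait values, which
reproduces the magnitude regime (tens) of published selection tables built
on raw-scale scores; the two scales order genotypes differently only
through the columns' differing variances, and the score-combination step
below is independent of the choice.

The comprehensive value is F = Σₖ wₖ Fₖ over the retained components with
wₖ = pₖ/Σₖpₖ, the **unrounded** normalized variance proportions. Rounding
the weights to two decimals (0.37/0.32/0.16/0.14) shifts F by several
tenths and no longer reproduces published selection sheets; with unrounded
weights every published F in the embedded reference table is reproduced
within ±0.01 (input rounding). Selection keeps genotypes whose F strictly
exceeds the check parent's.

## Sucrose-yield regression

Fitting is done on genotype means. `ols_fit` wraps statsmodels OLS with an
intercept; exactly collinear predictors are dropped deterministically
(later-listed column first) and reported as NA rows rather than raising —
the behaviour needed when both Brix and the near-affine sucrose content are
offered as candidates. `stepwise_select` is a bidirectional greedy search
starting from the full model. The default criterion is AIC, the convention
of the classical stepwise tools; BIC and a p-threshold mode (enter 0.05 /
remove 0.10) are provided. AIC is not selection-consistent — it retains a
no-effect predictor with asymptotic probability P(χ²₁ > 2) ≈ 0.16 — so
consistency-style checks (a null predictor excluded in ≥95% of replicates)
are run under BIC, the criterion for which that property holds; AIC remains
the default because it matches the tool convention and favours predictive
accuracy over sparsity.

The published four-trait equation SY = 2.01·SN + 8.32·SD + 0.79·B +
3.44·SH − 47.64 is exposed directly; evaluated at the population trait
means it returns 11.62 t/ha, within 1% of the observed mean sucrose yield.
An alternative three-trait variant (SN, B, SW) is included for
completeness, but evaluated at the same means it returns ≈3.6 t/ha — far
from the observed mean — so it is flagged as not recommended and excluded
from the reproduction checks. Validation of estimated against measured
yields reports the Pearson correlation, a two-sided variance-ratio F test
and a one-way ANOVA of means (equivalent to a two-sample t test), with an
"aa"/"ab" verdict at α = 0.05.

## The synthetic trial generator

The study population's plot-level data are not deposited, so the generator
emulates its structure from the published per-trait summary (means, SDs,
skewness, heritabilities of 135 genotype means over 2 years × 3 replicates).

* **Variance split.** For each trait the entry-mean variance σ² (the
  published SD squared) is split as σ²g = h²σ², with the non-genetic
  remainder divided equally between the G×E and residual entry-mean
  contributions: σ²ge = n·rem/2, σ²e = nr·rem/2. Plugging the split back
  into the heritability formula returns the target h² exactly (closed
  form); the formula-level example (8, 2, 6) at n = 2, r = 3 gives
  h² = 0.80.
* **Correlated genotypic effects.** An 8-trait Gaussian copula on the base
  traits; signs follow the population's reported trait relationships
  (TR–ETR +, SN–SD −, SD–SW +, IL–SH/B +), moderate magnitudes, projected
  to the nearest PSD correlation matrix.
* **Skewed traits.** TR, ETR and Brix carry log-normal genotypic effects;
  the log-normal shape is solved in closed form (Cardano) so the
  genotype-mean skewness matches the published value after dilution by the
  non-genetic variance share (target/h²^1.5 at the genotypic level).
  Finite-sample skewness estimates at m = 135 run somewhat below the
  generating value, as sample skewness of heavy-tailed data does.
* **Within-plot competition.** The G×E and residual draws carry a −0.6
  SN–SW correlation (all other noise independent). This is deliberate:
  denser stands produce lighter stalks, and without a plot-level tradeoff
  the product trait Y would average SN·SW·10 ≈ 87 t/ha, ~13% above the
  published 77.25, while pushing the whole tradeoff into the genotypic
  level would cancel genotypic variance of the product and drag its
  heritability to ~0.66, below the published 0.75. The split (genotypic
  −0.35, noise −0.6) reproduces both the product-trait means/SDs (SY
  12.4 ± 4.2 vs published 11.55 ± 4.06) and heritabilities (every trait's
  mean estimate in 0.76–0.84 vs published 0.75–0.84).
* **Sucrose content** is affine in Brix (slope = ratio of published SDs,
  small residual, σ = 0.2) — the published shape statistics of B and SC are
  identical, implying near-affine dependence.
* **Support bounds.** Draws that leave a trait's support (non-positive
  sizes, percentages outside (0, 100)) have their plot residual resampled,
  not truncated, avoiding point masses at the bounds.
* **Environment and blocks.** Environments get symmetric fixed offsets
  (±0.25 trait SD by default) so the seasonal effect is detectably real;
  block effects are Gaussian with SD 0.2 of the trait SD. Both cancel from
  pooled genotype means in a balanced design, so they do not disturb the
  genotype-mean calibration.
* **Check parent.** The elite check enters as one extra genotype whose
  latent genotypic score is pinned at the population's 80th percentile on
  every trait — a stable, above-average reference, so selection counts
  against it are meaningful across seeds.
* **Stalk diameter** is taken in cm (a 2.6 mm cane stalk is not
  biologically plausible; published tables of this trait occasionally
  miscapitalize the unit).

What the generator does **not** emulate: spatial field trends, ratoon
carry-over between seasons, genotype-specific error variances, and the full
empirical correlation structure (only the signed pairs listed above are
imposed; the published analysis found 30 significant trait pairs, while the
generator's sparser structure yields fewer). Consequently, tests passing on
synthetic populations demonstrate that the estimators recover what the
generator puts in — they cannot certify the study's own data-dependent
numbers (its exact cluster split 55/69/11, its 30 significant pairs, its
regression R² of 0.93), which are therefore covered by property checks
(oracle equivalences, selection consistency, coefficient-coverage rates)
rather than value reproduction.

## Numerical conventions and problem sizes

* Sigma-binning boundaries are half-open below; boundary values go up.
* Ward ties follow SciPy's deterministic ordering; cluster ids are
  renumbered by first appearance.
* PCA eigenvector signs are pinned by the sucrose-yield loading.
* Collinear regression columns are dropped later-listed-first.
* All generator randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical (config, design, seed) triples give
  byte-identical written tables.
* Monte-Carlo checks use 135-genotype trials with 200 seeds for
  heritability recovery (tolerance ±0.03 around 0.80) and 500 seeds for
  the product-trait correlation (±0.02 around the delta-method value
  0.913) and the Shannon regime (±0.05 around 2.98); these sizes hold the
  Monte-Carlo standard error near 0.001–0.003, an order of magnitude below
  each tolerance.

## Known limitations

* EMS components (not REML) assume balance; unbalanced field data must be
  completed or subset before analysis.
* The entropy estimator is the plug-in estimator; no bias correction or
  bootstrap CI is applied (the small-sample bias at m = 135, ≈0.04 bits,
  is documented above and folded into the expected regime).
* The raw-score PCA scale is provided for compatibility with published
  selection sheets; new analyses should prefer the standardized scale.
* The stepwise search is greedy; it matches exhaustive best-subset search
  on the small candidate sets used here (verified in tests) but carries no
  general optimality guarantee.
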