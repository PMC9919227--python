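# canepheno

Phenotypic diversity evaluation and selection computation for sugarcane
hybrid F₁ breeding populations.

Sugarcane breeding still leans on phenotypic selection: a cross between two
elite parents yields hundreds of F₁ seedlings, and the breeder must decide —
from a multi-environment field trial — which hybrids carry enough sucrose
yield potential to advance. `canepheno` implements the statistical workflow
for that decision on plot-level trait tables from a randomized
complete-block design (RCBD) grown across several seasons:

- **Synthetic trial generation** — a calibrated simulator of the
  135-hybrid × 2-year × 3-replicate trial structure (the study population's
  raw data are not publicly deposited), with correlated genotypic effects,
  G×E and residual strata, log-normal skewed traits, and product traits
  cane yield Y = SN·SW (t/ha) and sucrose yield SY = Y·SC.
- **Diversity statistics** — per-trait mean, SD, range, CV, skewness,
  kurtosis, and the Shannon–Wiener index H′ over ten half-σ classes
  spanning mean ± 2σ.
- **Heritability** — balanced RCBD ANOVA, expected-mean-squares variance
  components, and entry-mean broad-sense heritability
  h² = σ²g / (σ²g + σ²ge/n + σ²e/nr).
- **Correlation & clustering** — Pearson screening with significance tiers
  (\*, \*\*, \*\*\*), and Ward clustering of membership-standardized
  genotype means.
- **PCA selection** — correlation-matrix PCA, Kaiser retention (λ > 1), the
  comprehensive score F = Σₖ wₖFₖ with wₖ = pₖ/Σpₖ (unrounded variance
  proportions), and elite selection against a check parent.
- **Sucrose-yield model** — OLS and bidirectional stepwise regression, the
  published estimation equation
  `SY = 2.01·SN + 8.32·SD + 0.79·B + 3.44·SH − 47.64` (t/ha), and
  estimated-vs-measured validation.

## Worked example

```python
import canepheno as cp
from canepheno.reference import PC_PROPORTIONS, SELECTION_TABLE

# Published selection sheet: recombine each hybrid's four PC scores with
# variance-proportion weights and select everything above the check parent.
f = cp.composite_score(SELECTION_TABLE[["F1", "F2", "F3", "F4"]], PC_PROPORTIONS)
selected = cp.select_elite(f, "ROC22")
print(f"check parent ROC22: F = {f.loc['ROC22']:.2f}")
print(f"selected hybrids: {len(selected)}; best {selected.index[0]} "
      f"(F = {selected.iloc[0]:.2f})")
```

prints

```
check parent ROC22: F = 35.46
selected hybrids: 24; best F1-84 (F = 46.78)
```

meaning 24 of the 135 hybrids score a comprehensive PC value above the
elite check parent's 35.47 and advance to the next breeding stage, the best
of them (F1-84) by more than 11 points.

A full simulated-trial run:

```python
table = cp.simulate_trial(cp.default_config(), cp.TrialDesign(), seed=1)
print(cp.heritability_table(table)[["trait", "h2"]].round(2).to_string(index=False))
```

gives per-trait broad-sense heritabilities between 0.70 and 0.84 — the
regime in which genotype-mean selection is worthwhile. The `examples/`
directory holds one narrative script per capability
(`python examples/01_simulate_trial.py`, …), and the same stages are
scriptable from the shell:

```bash
canepheno simulate --genotypes 135 --seed 1 --out trial.csv
canepheno evaluate --in trial.csv --out summary.csv
canepheno heritability --in trial.csv --out varcomp.csv
canepheno pca-select --in trial.csv --check ROC22 --out selection.csv
canepheno fit-model --in trial.csv --candidates SN,SD,IL,SH,B --out model.json
canepheno run --out-dir results/   # the whole pipeline + report
```

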