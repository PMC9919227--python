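"""Comprehensive PCA score and elite selection against the check parent.

Part 1 recomputes the published selection table: each hybrid's comprehensive
value F is the variance-proportion-weighted sum of its four PC scores, and a
hybrid is selected when F beats the check parent ROC22.

Part 2 runs the same machinery end-to-end on a simulated population.
"""

import canepheno as cp
from canepheno.reference import PC_PROPORTIONS, SELECTION_TABLE

# -- Part 1: the published selection sheet ---------------------------------
f = cp.composite_score(SELECTION_TABLE[["F1", "F2", "F3", "F4"]], PC_PROPORTIONS)
selected = cp.select_elite(f, "ROC22")
print(f"check parent ROC22: F = {f.loc['ROC22']:.2f}")
print(f"selected hybrids: {len(selected)}; best {selected.index[0]} "
      f"(F = {selected.iloc[0]:.2f}), weakest {selected.index[-1]} "
      f"(F = {selected.iloc[-1]:.2f})")

# -- Part 2: selection on a fresh simulated population ---------------------
table = cp.simulate_trial(cp.default_config(), cp.TrialDesign(), seed=1)
means = cp.genotype_means(table)
result = cp.pca_select(means, check_id="ROC22")
model = cp.fit_pca(means)
print(f"\nsimulated population: eigenvalues {model.eigenvalues[:4].round(2)}, "
      f"{len(result.retained)} PCs retained (Kaiser), "
      f"cumulative {model.cumulative[len(result.retained) - 1]:.1f}%")
print(f"{int(result.table['selected'].sum())} hybrids exceed the check "
      f"(F = {result.check_f:.2f})")

print(
    "\nF condenses all retained PC axes into one ranking number; the check "
    "parent's F is the bar a progeny must clear to advance."
)
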