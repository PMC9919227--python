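"""Correlation screening and Ward clustering of the hybrid population.

Computes all 55 pairwise Pearson correlations of the 11 traits on pooled
genotype means with significance tiers, then cuts the Ward tree of
membership-standardized means into three groups and profiles them.
"""

import canepheno as cp

table = cp.simulate_trial(cp.default_config(), cp.TrialDesign(), seed=1)
means = cp.genotype_means(table)

corr = cp.correlate(means)
counts = corr.pair_counts()
print(f"significant pairs: {counts['significant']} of {corr.n_pairs} "
      f"(*** {counts['***']}, ** {counts['**']}, * {counts['*']}; "
      f"{counts['positive_significant']} positive, "
      f"{counts['negative_significant']} negative)")
print(f"strongest pair: Y-SY r = {corr.r.loc['Y', 'SY']:.2f} "
      "(sucrose yield is yield times sucrose content)")

clusters = cp.ward_cluster(cp.membership_standardize(means), k=3)
print("\ngroup sizes:", dict(clusters.group_sizes))
profile = cp.group_profile(clusters.labels, means)
print("\nper-group trait means (rank 1 = highest):")
print(profile.round(2).to_string())

print(
    "\nThe rank rows show each group's character, e.g. which group pairs "
    "tall/heavy stalks with high yield and which trades stalk size for "
    "tillering."
)
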