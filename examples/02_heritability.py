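"""Variance components and broad-sense heritability of every trait.

Fits the balanced RCBD ANOVA per trait, inverts the expected mean squares
into genotypic, genotype-by-environment and residual variances, and applies
the entry-mean heritability formula h2 = sg2 / (sg2 + sge2/n + se2/(n r)).
"""

import canepheno as cp

table = cp.simulate_trial(cp.default_config(), cp.TrialDesign(), seed=1)
varcomp = cp.heritability_table(table)
print(varcomp.round(3).to_string(index=False))

print(
    "\nh2 in the 0.7-0.85 range says genotype means are a reliable basis "
    "for selection; the environment F-test picks up the year effect."
)
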