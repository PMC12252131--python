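"""Decompose phenotypic variance: ANOVA, plasticity slopes, GGE axes.

The ANOVA variance % column is each stratum's share of the total sum of
squares; Finlay-Wilkinson slopes near 1 mean average plasticity (>1 more
responsive than the population, <1 more stable); the GGE axes summarize
genotype main effect plus genotype-by-environment interaction.
"""

import gxetools as g

trial = g.simulate_trial(n_lines=60, n_markers=300, seed=1, traits=["BW"])

anova = g.anova_decompose(trial.phenotypes, "BW")
print("ANOVA for boll weight (variance % = SS share of total):")
print(anova.round(3).to_string())

fw = g.fw_regression(trial.phenotypes, "BW")
print("\nFinlay-Wilkinson plasticity: slope mean "
      f"{fw.fits.slope.mean():.3f}, range "
      f"[{fw.fits.slope.min():.2f}, {fw.fits.slope.max():.2f}]")
print("five most plastic lines:")
print(fw.fits.nlargest(5, "slope").round(3).to_string())

gge = g.gge_biplot(trial.phenotypes, "BW")
print(f"\nGGE: axis 1 explains {100 * gge.explained_fraction[0]:.1f}%, "
      f"axis 2 {100 * gge.explained_fraction[1]:.1f}% of G+GxE variation")
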