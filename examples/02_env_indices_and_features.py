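"""Derive the 13 daily environmental factors and window features.

Eight base weather variables are expanded with five derived indices
(growing degree days, diurnal temperature range, precipitation per DTR,
photothermal quotient, photothermal time); a dense grid of 5-day window
means turns each environment's season into 1898 features.
"""

import gxetools as g

trial = g.simulate_trial(n_lines=10, n_markers=50, seed=1)
table = g.daily_factor_table(trial.weather)

print("daily factor table (first environment, days 70-72):")
env0 = table.env_id.iloc[0]
print(table.query("env_id == @env0 and 70 <= day <= 72").round(2).to_string(index=False))

feats = g.build_window_features(table, window_size=5, stride=1)
print(f"\nwindow feature matrix: {feats.shape[0]} environments x "
      f"{feats.shape[1]} features (146 windows x 13 factors)")
print("example column 'tmax_111_115' (mean tmax over days 111-115):")
print(feats["tmax_111_115"].round(2).to_string())

pcs = g.genotype_pcs(trial.genotypes, cum_threshold=0.90)
print(f"\ngenotype PCs: {pcs.k} components explain "
      f"{100 * pcs.cumulative_explained:.1f}% of marker variance")
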