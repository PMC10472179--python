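"""The survival stage: nested Cox models, trend tests and sensitivity fits.

Simulates a cohort with a known pro-inflammatory effect (log-HR 0.12 per DII
unit), then fits the three nested adjustment levels on women, exactly the
layout of a quintile hazard-ratio table.
"""

from diisurv import (ModelSpec, ScenarioConfig, run_model_levels, run_scenario,
                     sensitivity_analysis)

cohort, truth, _ = run_scenario(ScenarioConfig(n_subjects=4000), seed=42)
women = cohort[cohort["sex"] == "woman"]
print(f"women: n={len(women)}, events={int(women['event'].sum())}")

for level, (model, trend) in run_model_levels(women).items():
    cells = []
    for q in range(1, 6):
        row = model.table.loc[f"dii_quintile_q{q}"]
        cells.append("1 (ref)" if q == 1 else
                     f"{row.hr:.2f} ({row.ci_lower:.2f}-{row.ci_upper:.2f})")
    print(f"model {level}: " + " | ".join(cells) + f"   trend p={trend.p:.3f}")
# Hazard ratios compare each DII quintile against the least inflammatory
# quintile (Q1); a monotone rise with a small trend p indicates that fracture
# hazard increases with dietary inflammatory potential.

print("\nsensitivity (disease-exclusion) subsets, continuous DII HR per unit:")
for name, res in sensitivity_analysis(women, ModelSpec(covariate_level=3)).items():
    row = res.continuous_model.table.loc["dii"]
    print(f"  {name:<36} n={res.continuous_model.n:<5} "
          f"HR {row.hr:.2f} ({row.ci_lower:.2f}-{row.ci_upper:.2f})")
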