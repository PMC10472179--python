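"""Inspect the synthetic-cohort generator and its observation model.

Generates a cohort, shows how true Weibull event times are degraded into
questionnaire-style observations (integer recalled fracture age, reported at
the next attended survey wave), and verifies determinism under the seed.
"""

import pandas as pd

from diisurv import ScenarioConfig, run_scenario

cfg = ScenarioConfig(n_subjects=2000)
cohort, truth, log = run_scenario(cfg, seed=7)

print(log.summary())
print(f"\nevents: {int(cohort['event'].sum())} "
      f"({100 * cohort['event'].mean():.1f}% of retained; target regime ~7.5%)")
print(f"median follow-up: {cohort['person_time'].median():.1f} y")
print(f"DII median (IQR): {cohort['dii'].median():.2f} "
      f"({cohort['dii'].quantile(0.25):.2f} to {cohort['dii'].quantile(0.75):.2f})")

ev = cohort[cohort["event"]].head(5)
view = pd.DataFrame({
    "age_at_baseline": ev["age"],
    "recalled_fracture_age": ev["fracture_age"].astype(int),
    "person_time_reconstructed": ev["person_time"].round(2),
    "true_event_time": truth.loc[ev.index, "true_event_time"].round(2),
})
print("\nobservation model (first 5 events):")
print(view.to_string(index=False))
# person_time is rebuilt from the integer recalled age with a mid-year
# convention, so it sits within half a year of the true event time; the
# truth table exists only for validation and never enters the analysis.

again, _, _ = run_scenario(cfg, seed=7)
print(f"\nsame seed reproduces the cohort exactly: {cohort.equals(again)}")
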