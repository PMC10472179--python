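"""Dose-response with restricted cubic splines.

Fits the adjusted spline model for women and prints the hazard-ratio curve
against the sex-specific median DII (HR = 1 at the median by construction),
with tests for overall association and for departure from linearity.
"""

import numpy as np

from diisurv import ModelSpec, ScenarioConfig, fit_rcs, run_scenario

cohort, _, _ = run_scenario(ScenarioConfig(n_subjects=4000), seed=42)
women = cohort[cohort["sex"] == "woman"]

curve = fit_rcs(women, ModelSpec(exposure="rcs", covariate_level=3))
print(f"knots at DII = {np.round(curve.knots, 2)}")
print(f"reference (median DII) = {curve.reference:.2f}")
print(f"overall association p = {curve.overall_p:.4f}")
print(f"nonlinearity p        = {curve.nonlinearity_p:.4f}")

print("\n  DII     HR   95% CI")
for x in np.quantile(curve.grid, [0.05, 0.25, 0.5, 0.75, 0.95]):
    i = int(np.argmin(np.abs(curve.grid - x)))
    print(f"{curve.grid[i]:+6.2f}  {curve.hr[i]:5.2f}  "
          f"({curve.ci_lower[i]:.2f}-{curve.ci_upper[i]:.2f})")
# A small overall p with a large nonlinearity p says the hazard rises with
# the DII and a straight line on the log-hazard scale describes it
# adequately; HRs above 1 to the right of the median mark the
# pro-inflammatory range where fracture risk is elevated.
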