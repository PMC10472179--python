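import numpy as np
import pandas as pd
import pytest

from diisurv import (FitError, ModelSpec, SchemaError, UsageError,
                     check_proportional_hazards, component_dii_analysis,
                     default_knots, fit_cox, fit_rcs, make_stratifiers,
                     rcs_basis, run_model_levels, sensitivity_analysis,
                     sensitivity_subsets, subgroup_analysis, trend_test)
from tests.conftest import natural_spline_scalar


@pytest.fixture(scope="module")
def nested_fits(women_cohort):
    return run_model_levels(women_cohort, exposure="quintile", levels=(1, 2, 3))


class TestFitCox:
    def test_hr_ci_identity_every_row(self, nested_fits):
        """exp(beta +/- 1.96 se) must reproduce every printed CI bound."""
        for level, (model, _) in nested_fits.items():
            t = model.table.dropna(subset=["se"])
            np.testing.assert_allclose(t["ci_lower"], np.exp(t["beta"] - 1.96 * t["se"]),
                                       rtol=0, atol=1e-9)
            np.testing.assert_allclose(t["ci_upper"], np.exp(t["beta"] + 1.96 * t["se"]),
                                       rtol=0, atol=1e-9)
            np.testing.assert_allclose(t["hr"], np.exp(t["beta"]), atol=1e-12)

    def test_reference_quintile_hr_exactly_one(self, nested_fits):
        for level, (model, _) in nested_fits.items():
            ref = model.table.loc[model.reference_label]
            assert ref["hr"] == 1.0 and ref["beta"] == 0.0
            assert np.isnan(ref["se"]) and np.isnan(ref["ci_lower"])

    def test_log_likelihood_nondecreasing_across_nested_levels(self, nested_fits):
        ll = [nested_fits[k][0].log_likelihood for k in (1, 2, 3)]
        assert ll[0] <= ll[1] + 1e-8 <= ll[2] + 2e-8

    def test_positive_effect_recovered_with_continuous_exposure(self, sim_cohort):
        res = fit_cox(sim_cohort, ModelSpec(exposure="continuous", covariate_level=3))
        row = res.table.loc["dii"]
        # generating log-HR is 0.12/unit; estimate within 3 standard errors
        assert abs(row["beta"] - 0.12) < 3 * row["se"]

    def test_no_events_is_informative_failure(self, sim_cohort):
        dead = sim_cohort.copy()
        dead["event"] = False
        with pytest.raises(FitError, match="no events"):
            fit_cox(dead, ModelSpec(covariate_level=1))


class TestTrendTest:
    def test_strong_monotone_effect_detected(self):
        from diisurv import ScenarioConfig, run_scenario
        strong, _, _ = run_scenario(ScenarioConfig(n_subjects=2000, beta_dii=0.4),
                                    seed=321)
        tr = trend_test(strong, ModelSpec(covariate_level=3))
        assert tr.coef > 0
        assert tr.p < 0.01

    def test_constant_quintile_returns_missing_with_warning(self, women_cohort):
        flat = women_cohort.copy()
        flat["dii_quintile"] = 3
        with pytest.warns(UserWarning, match="constant"):
            tr = trend_test(flat, ModelSpec(covariate_level=3))
        assert np.isnan(tr.p)

    def test_integer_coding_available(self, women_cohort):
        tr = trend_test(women_cohort, ModelSpec(covariate_level=1, trend_coding="integer"))
        assert np.isfinite(tr.p)


class TestRCS:
    def test_basis_matches_truncated_power_oracle(self):
        knots = [-2.0, -0.5, 0.8, 2.5]
        grid = np.linspace(-4, 4, 10)
        basis = rcs_basis(grid, knots)
        for i, x in enumerate(grid):
            expected = natural_spline_scalar(float(x), knots)
            np.testing.assert_allclose(basis[i], expected, atol=1e-12)

    def test_linear_beyond_boundary_knots(self):
        knots = [0.0, 1.0, 2.0, 3.0]
        x = np.array([4.0, 5.0, 6.0])
        b = rcs_basis(x, knots)
        for col in range(1, b.shape[1]):
            slopes = np.diff(b[:, col])
            np.testing.assert_allclose(slopes, slopes[0], atol=1e-9)

    def test_bad_knots_rejected(self):
        with pytest.raises(Exception, match="strictly increasing"):
            rcs_basis([0.0], [1.0, 1.0, 2.0])
        with pytest.raises(Exception, match="3 knots"):
            rcs_basis([0.0], [1.0, 2.0])

    def test_curve_reference_hr_is_one_and_band_contains_estimate(self, women_cohort):
        curve = fit_rcs(women_cohort, ModelSpec(exposure="rcs", covariate_level=3))
        # evaluating the contrast at the reference must give exactly HR 1
        from diisurv.spline import rcs_basis as rb
        delta = rb(np.array([curve.reference]), curve.knots) - rb(
            np.array([curve.reference]), curve.knots)
        assert np.exp(delta @ curve.model.table.loc[
            list(curve.model.exposure_terms), "beta"].to_numpy())[0] == 1.0
        assert np.all(curve.ci_lower <= curve.hr + 1e-12)
        assert np.all(curve.hr <= curve.ci_upper + 1e-12)
        assert 0 < curve.overall_p <= 1 and 0 < curve.nonlinearity_p <= 1

    def test_knots_outside_range_rejected(self, women_cohort):
        with pytest.raises(UsageError, match="inside"):
            fit_rcs(women_cohort, ModelSpec(exposure="rcs", covariate_level=1),
                    knots=[-50.0, 0.0, 50.0])

    def test_default_knot_placement(self):
        x = np.linspace(0, 1, 1001)
        np.testing.assert_allclose(default_knots(x, 4), [0.05, 0.35, 0.65, 0.95],
                                   atol=1e-9)


class TestSubgroups:
    def test_constant_stratifier_named_in_error(self, women_cohort):
        s = pd.Series(True, index=women_cohort.index, name="always")
        with pytest.raises(FitError, match="always"):
            subgroup_analysis(women_cohort, s)

    def test_strata_partition_and_interaction_p(self, women_cohort):
        strat = make_stratifiers(women_cohort)
        res = subgroup_analysis(women_cohort, strat["age_ge_50"],
                                ModelSpec(covariate_level=3), name="age")
        ns = [s.model.n for s in res.strata.values() if s.model is not None]
        assert sum(ns) == len(women_cohort)
        assert 0 <= res.interaction_p <= 1

    def test_standard_stratifiers_are_binary(self, women_cohort):
        strat = make_stratifiers(women_cohort)
        assert set(strat.columns) == {"age_ge_50", "bmi_ge_24", "smoker", "drinker",
                                      "abdominal_obesity", "osta_le_minus1",
                                      "mamc_ge_split"}
        assert strat.dtypes.eq(bool).all()

    def test_fixed_mamc_split_override(self, women_cohort):
        strat = make_stratifiers(women_cohort, mamc_split=21.46)
        assert strat["mamc_ge_split"].equals(women_cohort["mamc"] >= 21.46)


class TestSensitivity:
    def test_truth_table_subset_sizes(self):
        # 8 rows: each (hypertension, diabetes) combination twice
        combos = [(h, d) for h in (False, True) for d in (False, True)] * 2
        cohort = pd.DataFrame({
            "hypertension": [h for h, _ in combos],
            "diabetes": [d for _, d in combos],
        })
        sizes = {k: len(v) for k, v in sensitivity_subsets(cohort).items()}
        assert sizes == {
            "non_hypertension": 4,
            "non_diabetes": 4,
            "non_hypertension_and_non_diabetes": 2,
            "non_hypertension_or_non_diabetes": 6,
        }

    def test_disease_free_cohort_subsets_equal_full(self, women_cohort):
        clean = women_cohort.copy()
        clean["hypertension"] = False
        clean["diabetes"] = False
        for sub in sensitivity_subsets(clean).values():
            assert len(sub) == len(clean)

    def test_full_analysis_runs_on_each_subset(self, women_cohort):
        out = sensitivity_analysis(women_cohort, ModelSpec(covariate_level=3))
        assert set(out) == {"non_hypertension", "non_diabetes",
                            "non_hypertension_and_non_diabetes",
                            "non_hypertension_or_non_diabetes"}
        for r in out.values():
            assert r.quintile_model.n <= len(women_cohort)
            assert np.isfinite(r.continuous_model.table.loc["dii", "beta"])


class TestComponents:
    def test_unknown_nutrient_lists_supported(self, women_cohort):
        with pytest.raises(UsageError, match="magnesium"):
            component_dii_analysis(women_cohort, "caffeine")

    def test_component_quintile_fit_and_trend(self, women_cohort):
        model, trend = component_dii_analysis(women_cohort, "protein")
        assert model.reference_label.endswith("q1")
        assert 0 <= trend.p <= 1

    def test_missing_component_column_is_schema_error(self, women_cohort):
        bare = women_cohort.drop(columns=["component_iron"])
        with pytest.raises(SchemaError, match="component_iron"):
            component_dii_analysis(bare, "iron")


class TestProportionalHazards:
    def test_single_exposure_model_diagnostics_shape(self, women_cohort):
        small = women_cohort.sample(500, random_state=1)
        res = fit_cox(small, ModelSpec(exposure="continuous", covariate_level=1))
        diag = check_proportional_hazards(res)
        assert diag.lrt_df == 1  # one exposure term -> one interaction term
        assert set(res._design.columns) - {"person_time", "event"} == set(diag.per_covariate.index)
        assert (0 <= diag.lrt_p <= 1) or np.isnan(diag.lrt_p)

    def test_time_flipped_effect_is_flagged(self):
        # effect reverses sign at t=5: strongly non-proportional
        rng = np.random.default_rng(8)
        n = 800
        x = rng.normal(size=n)
        # piecewise hazard: rate exp(1.2x) before t=5, exp(-1.2x) after
        t1 = rng.exponential(8.0 / np.exp(1.2 * x))
        t2 = 5 + rng.exponential(8.0 / np.exp(-1.2 * x))
        t = np.where(t1 < 5, t1, t2)
        e = t < 15
        t = np.minimum(t, 15)
        cohort = pd.DataFrame({"person_time": t, "event": e, "dii": x,
                               "age": rng.uniform(20, 70, n),
                               "sex": "woman",
                               "residence": rng.choice(["rural", "urban"], n),
                               "education": "none", "income": "q1",
                               "marital": "married"})
        res = fit_cox(cohort, ModelSpec(exposure="continuous", covariate_level=1))
        diag = check_proportional_hazards(res)
        assert diag.lrt_p < 0.05
        assert not diag.passed
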