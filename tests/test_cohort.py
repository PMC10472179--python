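import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from diisurv import (DomainError, ValidationError, apply_exclusions,
                     assign_quintiles, build_followup,
                     classify_abdominal_obesity, compute_bmi, compute_followup,
                     compute_mamc, compute_osta, derive_covariates)
from tests.conftest import brute_force_quintiles


class TestBMI:
    def test_hand_arithmetic_and_class(self):
        bmi, cls = compute_bmi(70.0, 175.0)
        assert bmi == pytest.approx(22.857, abs=1e-3)
        assert cls == "18.5-23.9"

    @pytest.mark.parametrize("bmi_target,expected", [
        (18.4, "<=18.4"), (18.5, "18.5-23.9"), (23.99, "18.5-23.9"),
        (24.0, "24.0-27.9"), (27.99, "24.0-27.9"), (28.0, ">=28.0"),
    ])
    def test_class_boundaries_left_inclusive(self, bmi_target, expected):
        # height 100 cm makes weight equal the BMI numerically
        assert compute_bmi(bmi_target, 100.0)[1] == expected

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(DomainError):
            compute_bmi(0.0, 175.0)


class TestMAMC:
    def test_25cm_muac_10mm_tsf_is_25_minus_pi(self):
        mamc, ok = compute_mamc(25.0, 10.0)
        assert mamc == pytest.approx(25.0 - math.pi, abs=1e-12)
        assert ok

    def test_zero_skinfold_returns_muac(self):
        assert compute_mamc(20.0, 0.0) == (20.0, True)

    def test_implausible_result_flagged(self):
        mamc, ok = compute_mamc(20.0, 70.0)  # 20 - 7*pi < 0
        assert mamc < 0 and not ok


class TestWHR:
    @pytest.mark.parametrize("sex,whr,expected", [
        ("man", 0.90, True), ("man", 0.899, False),
        ("woman", 0.85, True), ("woman", 0.84, False),
    ])
    def test_asian_cutoffs_boundary_inclusive(self, sex, whr, expected):
        got_whr, flag = classify_abdominal_obesity(sex, whr * 100, 100.0)
        assert got_whr == pytest.approx(whr)
        assert flag is expected

    def test_zero_hip_rejected(self):
        with pytest.raises(DomainError):
            classify_abdominal_obesity("man", 90.0, 0.0)


class TestOSTA:
    @pytest.mark.parametrize("weight,age,score,cls", [
        (60.0, 70.0, -2.0, "medium"),
        (50.0, 50.0, 0.0, "low"),
        (40.0, 65.0, -5.0, "high"),
    ])
    def test_score_and_class(self, weight, age, score, cls):
        got = compute_osta(weight, age)
        assert got[0] == pytest.approx(score)
        assert got[1] == cls

    def test_boundaries_default_to_medium(self):
        assert compute_osta(45.0, 50.0)[1] == "medium"   # score -1
        assert compute_osta(40.0, 60.0)[1] == "medium"   # score -4

    def test_outer_boundary_policy(self):
        assert compute_osta(45.0, 50.0, boundary_class="outer")[1] == "low"
        assert compute_osta(40.0, 60.0, boundary_class="outer")[1] == "high"


# --------------------------------------------------------------------------
# exclusion cascade: hand-enumerated 12-subject fixture
# --------------------------------------------------------------------------

def exclusion_fixture():
    base = dict(
        age=40, pregnant_or_nursing_or_disabled=False, fracture_reported=False,
        fracture_age=np.nan, baseline_fracture=False, prior_mi_stroke_tumor=False,
        height=160.0, weight=60.0, whr=0.8,
        baseline_date=pd.Timestamp("1997-09-01"),
        last_survey_date=pd.Timestamp("2015-09-01"),
    )
    rows, energy = [], []
    def add(e=2000.0, **kw):
        rows.append({**base, **kw})
        energy.append(e)

    add(age=17)                                            # 0: under-age
    add(pregnant_or_nursing_or_disabled=True, e=600.0)     # 1: pregnancy wins over energy
    add(fracture_reported=np.nan)                          # 2: missing outcome
    add(last_survey_date=pd.Timestamp("1997-09-01"))       # 3: zero follow-up
    add(e=699.0)                                           # 4: energy < 700
    add(e=5001.0)                                          # 5: energy > 5000
    add(baseline_fracture=True)                            # 6: prevalent fracture
    add(prior_mi_stroke_tumor=True)                        # 7: disease history
    add(height=95.0)                                       # 8: body-measurement outlier
    add(e=700.0)                                           # 9: boundary retained
    add(e=5000.0)                                          # 10: boundary retained
    add()                                                  # 11: clean
    subjects = pd.DataFrame(rows)
    return subjects, pd.Series(energy, index=subjects.index)


EXPECTED_TALLIES = {
    "age_under_minimum": 1,
    "pregnant_nursing_disabled": 1,
    "missing_outcome_or_followup": 2,
    "implausible_energy": 2,
    "baseline_fracture": 1,
    "prior_mi_stroke_tumor": 1,
    "body_measurement_outlier": 1,
}


class TestExclusions:
    def test_hand_enumerated_counts(self):
        subjects, energy = exclusion_fixture()
        retained, log = apply_exclusions(subjects, energy)
        assert log.counts == EXPECTED_TALLIES
        assert log.n_retained == 3
        assert sorted(retained.index) == [9, 10, 11]
        assert log.n_retained + sum(log.counts.values()) == log.n_input

    def test_first_rule_precedence(self):
        subjects, energy = exclusion_fixture()
        _, log = apply_exclusions(subjects, energy)
        # subject 1 is pregnant AND has implausible energy; charged to pregnancy
        assert log.first_failing_rule.iloc[1] == "pregnant_nursing_disabled"

    def test_idempotent_on_own_output(self):
        subjects, energy = exclusion_fixture()
        retained, _ = apply_exclusions(subjects, energy)
        again, log2 = apply_exclusions(retained, energy.loc[retained.index])
        assert len(again) == len(retained)
        assert sum(log2.counts.values()) == 0

    def test_summary_mentions_every_rule(self):
        subjects, energy = exclusion_fixture()
        _, log = apply_exclusions(subjects, energy)
        text = log.summary()
        assert "retained: 3" in text
        for rule in EXPECTED_TALLIES:
            assert rule.replace("_", " ") in text


# --------------------------------------------------------------------------
# quintiles
# --------------------------------------------------------------------------

class TestQuintiles:
    def test_ten_distinct_scores_two_per_group(self):
        s = pd.Series([3.0, 1.0, 4.0, 1.5, 9.0, 2.6, 5.3, 5.8, 9.7, 0.3])
        q = assign_quintiles(s, pd.Series(["a"] * 10))
        assert sorted(q.value_counts()) == [2, 2, 2, 2, 2]

    def test_monotone_in_score(self):
        rng = np.random.default_rng(0)
        s = pd.Series(rng.normal(size=200))
        q = assign_quintiles(s, pd.Series(["x"] * 200))
        order = s.sort_values().index
        assert q.loc[order].is_monotonic_increasing

    @given(st.lists(st.integers(0, 6), min_size=5, max_size=60))
    def test_matches_brute_force_with_ties(self, values):
        s = pd.Series([float(v) for v in values])
        q = assign_quintiles(s, pd.Series(["x"] * len(s)))
        assert q.tolist() == brute_force_quintiles(s.tolist())

    def test_stratified_by_sex(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.normal(size=100))
        sex = pd.Series(np.where(np.arange(100) % 2 == 0, "man", "woman"))
        q = assign_quintiles(s, sex)
        for g in ("man", "woman"):
            sub_q = assign_quintiles(s[sex == g], sex[sex == g])
            pd.testing.assert_series_equal(q[sex == g], sub_q)

    def test_small_stratum_rejected(self):
        with pytest.raises(ValidationError, match="at least 5"):
            assign_quintiles(pd.Series([1.0, 2.0, 3.0, 4.0]), pd.Series(["a"] * 4))


# --------------------------------------------------------------------------
# follow-up
# --------------------------------------------------------------------------

class TestFollowup:
    FINAL = pd.Timestamp("2015-09-01")

    def test_event_with_midyear_convention(self):
        rec = compute_followup(
            baseline_date="1997-09-01", age=40, last_survey_date="2015-09-01",
            fracture_reported=True, fracture_age=46, final_wave_date=self.FINAL)
        assert rec.event
        assert rec.person_time == pytest.approx(6.5, abs=0.01)

    def test_censored_at_final_wave(self):
        rec = compute_followup(
            baseline_date="1997-09-01", age=40, last_survey_date="2015-09-01",
            fracture_reported=False, fracture_age=None, final_wave_date=self.FINAL)
        assert not rec.event
        assert rec.end_date == self.FINAL
        assert rec.person_time == pytest.approx(18.0, abs=0.01)

    def test_censored_at_last_attended_wave(self):
        rec = compute_followup(
            baseline_date="1997-09-01", age=40, last_survey_date="2006-09-01",
            fracture_reported=False, fracture_age=None, final_wave_date=self.FINAL)
        assert rec.person_time == pytest.approx(9.0, abs=0.01)

    def test_prevalent_fracture_rejected(self):
        with pytest.raises(ValidationError, match="prevalent"):
            compute_followup(
                baseline_date="1997-09-01", age=40, last_survey_date="2015-09-01",
                fracture_reported=True, fracture_age=38, final_wave_date=self.FINAL)

    def test_vectorised_matches_scalar(self):
        subjects = pd.DataFrame({
            "baseline_date": [pd.Timestamp("1997-09-01")] * 3,
            "age": [40, 55, 30],
            "last_survey_date": [pd.Timestamp("2015-09-01"),
                                 pd.Timestamp("2009-09-01"),
                                 pd.Timestamp("2011-09-01")],
            "fracture_reported": [True, False, True],
            "fracture_age": [46.0, np.nan, 31.0],
        })
        table = build_followup(subjects, self.FINAL)
        for i, row in subjects.iterrows():
            rec = compute_followup(row["baseline_date"], row["age"],
                                   row["last_survey_date"], bool(row["fracture_reported"]),
                                   row["fracture_age"], self.FINAL)
            assert table.loc[i, "person_time"] == pytest.approx(rec.person_time, abs=1e-9)
            assert bool(table.loc[i, "event"]) == rec.event
        assert (table["person_time"] >= 0).all()

    def test_person_time_sum_invariant_under_reordering(self):
        rng = np.random.default_rng(5)
        n = 40
        subjects = pd.DataFrame({
            "baseline_date": [pd.Timestamp("1997-09-01")] * n,
            "age": rng.integers(20, 70, n),
            "last_survey_date": pd.Timestamp("1997-09-01")
            + pd.to_timedelta(rng.integers(400, 6500, n), unit="D"),
            "fracture_reported": [False] * n,
            "fracture_age": [np.nan] * n,
        })
        a = build_followup(subjects, self.FINAL)["person_time"].sum()
        b = build_followup(subjects.sample(frac=1, random_state=0), self.FINAL)["person_time"].sum()
        assert a == pytest.approx(b, abs=1e-9)


def test_derive_covariates_pure_and_consistent():
    subjects = pd.DataFrame({
        "sex": ["man", "woman"], "age": [70, 50],
        "height": [175.0, 160.0], "weight": [70.0, 45.0],
        "muac": [25.0, 23.0], "tsf": [10.0, 16.0],
        "waist": [90.0, 84.0], "hip": [100.0, 100.0],
    })
    a = derive_covariates(subjects)
    b = derive_covariates(subjects)
    pd.testing.assert_frame_equal(a, b)
    assert a.loc[0, "mamc"] == pytest.approx(25 - math.pi)
    assert bool(a.loc[0, "abdominal_obesity"])       # man at exactly 0.90
    assert not bool(a.loc[1, "abdominal_obesity"])   # woman at 0.84
    assert a.loc[1, "osta"] == pytest.approx(-1.0)
    assert a.loc[1, "osta_class"] == "medium"
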