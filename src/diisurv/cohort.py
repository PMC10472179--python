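"""Cohort derivation: anthropometric indices, exclusion cascade, sex-specific
exposure quintiles, and person-time construction.

Conventions
-----------
* BMI classes follow the Chinese adult cut points (under/normal/overweight/
  obese at 18.5, 24.0, 28.0 kg/m^2).
* Abdominal obesity uses the WHO Asian waist-to-hip ratio cutoffs, boundary
  inclusive: >= 0.90 for men, >= 0.85 for women.
* OSTA (Osteoporosis Self-assessment Tool for Asians) is
  0.2 x (weight[kg] - age[y]); risk classes low (> -1), medium ([-4, -1]),
  high (< -4). The boundary values -1 and -4 are assigned to the medium
  class by default (configurable).
* Follow-up runs from the baseline survey to the first of: reconstructed
  fracture date, last attended survey, or the final administrative wave.
  Fracture timing is questionnaire-recalled as an integer age, reconstructed
  with a mid-year (+0.5 y) convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

DAYS_PER_YEAR = 365.25

BMI_CLASS_LABELS = ("<=18.4", "18.5-23.9", "24.0-27.9", ">=28.0")
BMI_CLASS_EDGES = (18.5, 24.0, 28.0)

WHR_CUTOFFS = {"man": 0.90, "woman": 0.85}

OSTA_CLASS_LABELS = ("low", "medium", "high")


# --------------------------------------------------------------------------
# anthropometric indices
# --------------------------------------------------------------------------

def compute_bmi(weight: float, height: float) -> tuple[float, str]:
    """BMI = weight(kg) / height(m)^2, with its 4-level class.

    ``height`` is in cm. Class edges are left-inclusive: 24.00 kg/m^2 falls
    in the 24.0-27.9 class.
    """
    if not (weight > 0 and height > 0):
        raise DomainError("weight and height must be > 0")
    bmi = weight / (height / 100.0) ** 2
    idx = int(np.searchsorted(BMI_CLASS_EDGES, bmi, side="right"))
    return bmi, BMI_CLASS_LABELS[idx]


def compute_mamc(muac: float, tsf: float) -> tuple[float, bool]:
    """Midarm muscle circumference: MUAC(cm) - pi x (TSF(mm) / 10).

    TSF is recorded in millimetres; the /10 converts it to cm. Returns
    ``(mamc, plausible)``; a non-positive result is arithmetically valid but
    flagged implausible.
    """
    if not (muac > 0):
        raise DomainError("muac must be > 0")
    if tsf < 0:
        raise DomainError("tsf must be >= 0")
    mamc = muac - math.pi * (tsf / 10.0)
    return mamc, mamc > 0


def classify_abdominal_obesity(sex: str, waist: float, hip: float) -> tuple[float, bool]:
    """Waist-to-hip ratio and the sex-specific abdominal-obesity flag.

    Boundary inclusive: a man at exactly WHR 0.90 (woman at 0.85) is obese.
    """
    if sex not in WHR_CUTOFFS:
        raise DomainError(f"sex must be one of {tuple(WHR_CUTOFFS)}, got {sex!r}")
    if not (waist > 0 and hip > 0):
        raise DomainError("waist and hip must be > 0")
    whr = waist / hip
    return whr, bool(whr >= WHR_CUTOFFS[sex])


def compute_osta(weight: float, age: float,
                 *, boundary_class: str = "medium") -> tuple[float, str]:
    """OSTA score 0.2 x (weight - age) with its 3-level risk class.

    ``boundary_class`` controls where the exact values -1 and -4 fall
    ('medium' keeps the closed interval [-4, -1] medium; 'outer' pushes them
    to low and high respectively).
    """
    if not (weight > 0 and age > 0):
        raise DomainError("weight and age must be > 0")
    osta = 0.2 * (weight - age)
    if boundary_class == "medium":
        if osta < -4:
            cls = "high"
        elif osta <= -1:
            cls = "medium"
        else:
            cls = "low"
    elif boundary_class == "outer":
        if osta <= -4:
            cls = "high"
        elif osta < -1:
            cls = "medium"
        else:
            cls = "low"
    else:
        raise DomainError("boundary_class must be 'medium' or 'outer'")
    return osta, cls


def derive_covariates(subjects: pd.DataFrame) -> pd.DataFrame:
    """Vectorised covariate derivation on a subject table.

    Adds bmi, bmi_class, mamc, mamc_plausible, whr, abdominal_obesity, osta,
    osta_class. Pure: same input rows always give the same output.
    """
    out = subjects.copy()
    h = out["height"].to_numpy(dtype=float)
    w = out["weight"].to_numpy(dtype=float)
    out["bmi"] = w / (h / 100.0) ** 2
    out["bmi_class"] = pd.Categorical.from_codes(
        np.searchsorted(BMI_CLASS_EDGES, out["bmi"].to_numpy(), side="right"),
        categories=list(BMI_CLASS_LABELS), ordered=True,
    )
    mamc = out["muac"].to_numpy(dtype=float) - math.pi * (out["tsf"].to_numpy(dtype=float) / 10.0)
    out["mamc"] = mamc
    out["mamc_plausible"] = mamc > 0
    whr = out["waist"].to_numpy(dtype=float) / out["hip"].to_numpy(dtype=float)
    out["whr"] = whr
    cutoff = out["sex"].map(WHR_CUTOFFS).to_numpy(dtype=float)
    out["abdominal_obesity"] = whr >= cutoff
    osta = 0.2 * (w - out["age"].to_numpy(dtype=float))
    out["osta"] = osta
    out["osta_class"] = pd.Categorical(
        np.where(osta < -4, "high", np.where(osta <= -1, "medium", "low")),
        categories=list(OSTA_CLASS_LABELS), ordered=True,
    )
    return out


# --------------------------------------------------------------------------
# exclusion cascade
# --------------------------------------------------------------------------

@dataclass
class ExclusionConfig:
    """Plausibility windows and energy bounds for the exclusion cascade.

    Energy bounds are applied as strict inequalities (excluded when
    energy < 700 or energy > 5000 kcal/d), so the printed boundary values
    themselves are retained.
    """

    min_age: float = 18.0
    energy_low: float = 700.0
    energy_high: float = 5000.0
    height_range: tuple[float, float] = (100.0, 220.0)
    weight_range: tuple[float, float] = (25.0, 200.0)
    whr_range: tuple[float, float] = (0.5, 1.5)


EXCLUSION_RULES = (
    "age_under_minimum",
    "pregnant_nursing_disabled",
    "missing_outcome_or_followup",
    "implausible_energy",
    "baseline_fracture",
    "prior_mi_stroke_tumor",
    "body_measurement_outlier",
)


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts and each subject's first failing rule."""

    n_input: int
    n_retained: int
    counts: dict
    first_failing_rule: pd.Series  # indexed by subject_id; NaN for retained

    def summary(self) -> str:
        lines = [f"subjects assessed: {self.n_input}"]
        remaining = self.n_input
        for rule in EXCLUSION_RULES:
            k = self.counts.get(rule, 0)
            remaining -= k
            lines.append(f"  - excluded ({rule.replace('_', ' ')}): {k}  -> {remaining}")
        lines.append(f"retained: {self.n_retained}")
        return "\n".join(lines)



def _flag(s: pd.Series) -> pd.Series:
    """Missing-tolerant boolean coercion (NA counts as False)."""
    return s.astype("boolean").fillna(False).astype(bool)

def _missing_followup(subjects: pd.DataFrame) -> pd.Series:
    """Missing or unusable outcome/follow-up data.

    Covers: missing fracture report; fracture reported without an age; no
    last-attended survey; and zero follow-up (the last attended survey is not
    after baseline).
    """
    nat = pd.Series(pd.NaT, index=subjects.index)
    nan = pd.Series(np.nan, index=subjects.index)
    last = pd.to_datetime(subjects.get("last_survey_date", nat))
    mask = (
        subjects["fracture_reported"].isna()
        | (_flag(subjects["fracture_reported"])
           & subjects.get("fracture_age", nan).isna())
        | last.isna()
    )
    if "baseline_date" in subjects.columns:
        mask = mask | (last <= pd.to_datetime(subjects["baseline_date"]))
    return mask


def apply_exclusions(subjects: pd.DataFrame, energy: pd.Series,
                     config: ExclusionConfig | None = None
                     ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the ordered exclusion cascade; never raises on data content.

    ``energy`` is daily energy intake (kcal) aligned to ``subjects`` by
    index; a missing value counts as implausible energy. Each subject is
    charged to the first rule it violates, so per-rule counts sum to the
    number excluded and the cascade is idempotent on its own output.
    """
    cfg = config or ExclusionConfig()
    required = ("age", "pregnant_or_nursing_or_disabled", "fracture_reported",
                "baseline_fracture", "prior_mi_stroke_tumor",
                "height", "weight", "whr")
    missing = [c for c in required if c not in subjects.columns]
    if missing:
        raise SchemaError(f"subject table is missing columns: {missing}")

    e = energy.reindex(subjects.index).astype(float)
    checks = {
        "age_under_minimum": subjects["age"] < cfg.min_age,
        "pregnant_nursing_disabled": _flag(subjects["pregnant_or_nursing_or_disabled"]),
        "missing_outcome_or_followup": _missing_followup(subjects),
        "implausible_energy": e.isna() | (e < cfg.energy_low) | (e > cfg.energy_high),
        "baseline_fracture": _flag(subjects["baseline_fracture"]),
        "prior_mi_stroke_tumor": _flag(subjects["prior_mi_stroke_tumor"]),
        "body_measurement_outlier": (
            ~subjects["height"].between(*cfg.height_range)
            | ~subjects["weight"].between(*cfg.weight_range)
            | ~subjects["whr"].between(*cfg.whr_range)
        ),
    }
    first = pd.Series(pd.NA, index=subjects.index, dtype="object")
    for rule in EXCLUSION_RULES:
        mask = _flag(checks[rule]) & first.isna()
        first[mask] = rule
    retained = subjects[first.isna()]
    counts = {rule: int((first == rule).sum()) for rule in EXCLUSION_RULES}
    logrec = ExclusionLog(
        n_input=len(subjects), n_retained=len(retained),
        counts=counts, first_failing_rule=first,
    )
    assert logrec.n_retained + sum(counts.values()) == logrec.n_input
    return retained, logrec


# --------------------------------------------------------------------------
# exposure quintiles
# --------------------------------------------------------------------------

def assign_quintiles(scores: pd.Series, strata: pd.Series, *, n_groups: int = 5) -> pd.Series:
    """Rank-based quintiles within each stratum (typically sex).

    The sorted scores of a stratum are sliced into ``n_groups`` contiguous
    blocks whose sizes differ by at most one (earlier blocks take the
    remainder); tied scores all receive the label of the block containing
    the first sorted occurrence of that value, so labels are monotone in the
    score. Returns integer labels 1..n_groups.
    """
    if len(scores) != len(strata):
        raise SchemaError("scores and strata must be aligned")
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    for _, idx in strata.groupby(strata).groups.items():
        s = scores.loc[idx]
        if s.isna().any():
            raise ValidationError("quintile assignment requires non-missing scores")
        n = len(s)
        if n < n_groups:
            raise ValidationError(
                f"stratum has only {n} subjects; at least {n_groups} required"
            )
        order = np.argsort(s.to_numpy(), kind="stable")
        # block of the i-th sorted position; sizes differ by <= 1
        block = (np.arange(n) * n_groups) // n
        ranked_vals = s.to_numpy()[order]
        # ties share the label of their first occurrence
        first_block = pd.Series(block).groupby(ranked_vals).transform("min").to_numpy()
        labels = np.empty(n, dtype=float)
        labels[order] = first_block + 1
        out.loc[idx] = labels
    return out.astype(int)


# --------------------------------------------------------------------------
# person-time and events
# --------------------------------------------------------------------------

@dataclass
class FollowupConfig:
    """Conventions for reconstructing event dates from recalled ages.

    ``mid_year_offset`` places the event this fraction of a year after the
    birthday implied by the integer recalled age (0.5 = mid-year).
    """

    mid_year_offset: float = 0.5


@dataclass(frozen=True)
class FollowupRecord:
    person_time: float  # years
    event: bool
    end_date: pd.Timestamp


def compute_followup(baseline_date, age: float, last_survey_date,
                     fracture_reported: bool, fracture_age,
                     final_wave_date, config: FollowupConfig | None = None
                     ) -> FollowupRecord:
    """Build one subject's person-time and event indicator.

    Follow-up ends at the first of: the reconstructed fracture date, the last
    attended survey, or the final administrative wave. The fracture date is
    ``baseline_date + (fracture_age - floor(age) + mid_year_offset)`` years,
    treating the baseline as birthday-aligned (ages are questionnaire
    integers). A fracture age below the baseline age is a prevalent case and
    raises :class:`ValidationError`. If the reconstructed date lands after
    the censor date (possible within half a survey interval), the event is
    kept and person-time capped at the censor date.
    """
    cfg = config or FollowupConfig()
    baseline_date = pd.Timestamp(baseline_date)
    censor = min(pd.Timestamp(last_survey_date), pd.Timestamp(final_wave_date))
    if censor < baseline_date:
        raise ValidationError("censor date precedes baseline date")
    if fracture_reported:
        if fracture_age is None or (isinstance(fracture_age, float) and math.isnan(fracture_age)):
            raise ValidationError("fracture reported without a fracture age")
        offset_years = (float(fracture_age) - math.floor(age)) + cfg.mid_year_offset
        if offset_years < 0:
            raise ValidationError(
                f"fracture age {fracture_age} precedes baseline age {age}: prevalent case"
            )
        event_date = baseline_date + pd.Timedelta(days=round(offset_years * DAYS_PER_YEAR))
        end = min(event_date, censor)
        event = True
    else:
        end = censor
        event = False
    person_time = (end - baseline_date).days / DAYS_PER_YEAR
    return FollowupRecord(person_time=person_time, event=event, end_date=end)


def build_followup(subjects: pd.DataFrame, final_wave_date,
                   config: FollowupConfig | None = None) -> pd.DataFrame:
    """Vectorised :func:`compute_followup` over a subject table.

    Needs columns baseline_date, age, last_survey_date, fracture_reported,
    fracture_age. Returns a frame with person_time, event, end_date.
    """
    cfg = config or FollowupConfig()
    base = pd.to_datetime(subjects["baseline_date"])
    censor = pd.to_datetime(subjects["last_survey_date"]).clip(upper=pd.Timestamp(final_wave_date))
    if (censor < base).any():
        raise ValidationError("censor date precedes baseline date for some subjects")
    reported = _flag(subjects["fracture_reported"])
    fage = subjects["fracture_age"].astype(float)
    if (reported & fage.isna()).any():
        raise ValidationError("fracture reported without a fracture age")
    offset = (fage - np.floor(subjects["age"].astype(float))) + cfg.mid_year_offset
    if (reported & (offset < 0)).any():
        raise ValidationError("fracture age precedes baseline age: prevalent case(s) present")
    event_date = base + pd.to_timedelta(
        np.round(offset.fillna(0) * DAYS_PER_YEAR), unit="D"
    )
    end = censor.where(~reported, pd.concat([event_date, censor], axis=1).min(axis=1))
    out = pd.DataFrame(index=subjects.index)
    out["person_time"] = (end - base).dt.days / DAYS_PER_YEAR
    out["event"] = reported
    out["end_date"] = end
    assert (out["person_time"] >= 0).all()
    return out
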