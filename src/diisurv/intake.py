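"""Turn raw dietary recall records into per-subject nutrient profiles.

Two input modes mirror common survey data layouts:

* **food mode** — long records of grams of foods consumed per subject-day,
  joined against a food-composition table (nutrients per 100 g);
* **nutrient mode** — per-subject-day nutrient totals, already composed.

The recall window emulates a multi-day 24-hour review (typically 3 days);
per-day totals are averaged, unweighted by default, into one
:class:`~diisurv.profiles.NutrientProfile` per subject.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FoodLookupError, MissingDataError, SchemaError
from .profiles import ENERGY, NutrientProfile

log = logging.getLogger(__name__)

RECORD_COLUMNS = ("subject_id", "day_index", "item", "amount")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"recall records are missing columns: {missing}")
    if (records["amount"] < 0).any():
        raise SchemaError("recall record amounts must be >= 0")


def compose_nutrients(records: pd.DataFrame, fct: pd.DataFrame,
                      *, strict: bool = True) -> pd.DataFrame:
    """Convert food-mode records into per-subject-day nutrient totals.

    ``fct`` is the food-composition table: indexed by food identifier with
    nutrient columns holding amounts per 100 g (including energy in kcal per
    100 g). Each record contributes amount/100 x per-100 g values; a day with
    no resolvable foods yields all-zero totals.

    In strict mode an unresolvable food identifier raises
    :class:`FoodLookupError`; in lenient mode the rows are dropped and logged.
    """
    _check_records(records)
    if (fct.to_numpy(dtype=float) < 0).any():
        raise SchemaError("food composition values must be >= 0")
    pairs = records[["subject_id", "day_index"]].drop_duplicates()
    known = records["item"].isin(fct.index)
    if not known.all():
        bad = records.loc[~known, "item"].unique().tolist()
        if strict:
            raise FoodLookupError(bad)
        log.warning("dropping %d records with unknown foods: %s", (~known).sum(), bad)
        records = records[known]
    per100 = fct.loc[records["item"]].to_numpy(dtype=float)
    contrib = per100 * (records["amount"].to_numpy(dtype=float)[:, None] / 100.0)
    contrib = pd.DataFrame(contrib, columns=fct.columns, index=records.index)
    contrib[["subject_id", "day_index"]] = records[["subject_id", "day_index"]]
    totals = contrib.groupby(["subject_id", "day_index"]).sum()
    # preserve empty days: subject-days whose every row was dropped still get
    # an all-zero totals row
    totals = totals.reindex(pd.MultiIndex.from_frame(pairs), fill_value=0.0).sort_index()
    return totals


def aggregate_recalls(day_totals: pd.DataFrame,
                      *, weights: Sequence[float] | None = None,
                      expected_days: int | None = None,
                      strict: bool = False) -> pd.DataFrame:
    """Average per-day totals into one row per subject.

    ``day_totals`` is indexed by (subject_id, day_index) as produced by
    :func:`compose_nutrients` (nutrient-mode input can be supplied directly
    in the same layout). The default is the unweighted arithmetic mean across
    available days; ``weights`` (one per day_index position, e.g. 2/7-weekday
    5/7-weekend schemes) enables weighted averaging.

    Subjects with fewer than ``expected_days`` days are an error in strict
    mode, otherwise averaged over available days with a log entry. A subject
    with zero days raises :class:`MissingDataError`.
    """
    if day_totals.empty:
        raise MissingDataError("no recall days present for any subject")
    if weights is None:
        mean = day_totals.groupby(level="subject_id").mean()
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise DomainError("weights must be >= 0 with a positive sum")

        def _wmean(g: pd.DataFrame) -> pd.Series:
            k = len(g)
            w = weights[:k]
            return pd.Series(np.average(g.to_numpy(dtype=float), axis=0, weights=w),
                             index=g.columns)

        mean = day_totals.groupby(level="subject_id").apply(_wmean)
    if expected_days is not None:
        counts = day_totals.groupby(level="subject_id").size()
        short = counts[counts < expected_days]
        if len(short):
            if strict:
                raise MissingDataError(
                    f"subjects with fewer than {expected_days} recall days: "
                    f"{short.index.tolist()}"
                )
            log.warning("subjects averaged over fewer than %d days: %s",
                        expected_days, short.index.tolist())
    return mean


def profiles_from_means(mean_table: pd.DataFrame, *, energy_col: str = ENERGY):
    """Yield per-subject :class:`NutrientProfile` objects from a mean-intake table.

    Energy is read from ``energy_col`` (default the canonical ``energy``
    parameter, kcal/day) and carried both as the profile's ``energy_kcal``
    and as an intake so the per-day index can include it.
    """
    if energy_col not in mean_table.columns:
        raise SchemaError(f"mean intake table lacks the energy column {energy_col!r}")
    for sid, row in mean_table.iterrows():
        intakes = {c: float(v) for c, v in row.items() if pd.notna(v)}
        yield NutrientProfile(subject_id=sid, intakes=intakes,
                              energy_kcal=float(row[energy_col]), basis="per_day")


def energy_density_transform(profile: NutrientProfile) -> NutrientProfile:
    """Convert a per-day profile to per-1000 kcal densities.

    Each intake is divided by energy/1000; the energy parameter itself is
    removed (its density is the constant 1000). Homogeneous of degree zero:
    scaling all intakes and energy by the same factor leaves the result
    unchanged.
    """
    if profile.basis != "per_day":
        raise DomainError("energy_density_transform needs a per_day profile")
    if profile.energy_kcal is None or profile.energy_kcal <= 0:
        raise DomainError("energy_kcal must be > 0")
    factor = profile.energy_kcal / 1000.0
    dens = {p: x / factor for p, x in profile.intakes.items() if p != ENERGY}
    return NutrientProfile(subject_id=profile.subject_id, intakes=dens,
                           energy_kcal=None, basis="per_1000kcal")
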