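"""Per-subject nutrient intake profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .errors import DomainError, SchemaError, ValidationError

BASES = ("per_day", "per_1000kcal")

ENERGY = "energy"


@dataclass(frozen=True)
class NutrientProfile:
    """One subject's mean daily intake per food parameter.

    ``intakes`` maps parameter name to mean daily amount (or amount per
    1000 kcal when ``basis == 'per_1000kcal'``). ``energy_kcal`` is total
    daily energy; required and positive in the per-day basis.
    """

    subject_id: object
    intakes: Mapping[str, float]
    energy_kcal: float | None = None
    basis: str = "per_day"

    def __post_init__(self):
        if self.basis not in BASES:
            raise ValidationError(f"basis must be one of {BASES}, got {self.basis!r}")
        for name, x in self.intakes.items():
            if not math.isfinite(x) or x < 0:
                raise ValidationError(f"{self.subject_id}: intake of {name!r} must be finite and >= 0")
        if self.basis == "per_day":
            if self.energy_kcal is None or not math.isfinite(self.energy_kcal) or self.energy_kcal <= 0:
                raise DomainError(
                    f"{self.subject_id}: energy_kcal must be > 0 in the per_day basis"
                )
        object.__setattr__(self, "intakes", dict(self.intakes))


def profiles_to_table(profiles) -> pd.DataFrame:
    """Stack profiles into a wide table (one row per subject)."""
    rows = []
    for p in profiles:
        row = {"subject_id": p.subject_id, "energy_kcal": p.energy_kcal, **p.intakes}
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def profiles_from_table(table: pd.DataFrame, *, basis: str = "per_day"):
    """Inverse of :func:`profiles_to_table`; yields :class:`NutrientProfile`."""
    if "energy_kcal" not in table.columns and basis == "per_day":
        raise SchemaError("profile table needs an 'energy_kcal' column in the per_day basis")
    nutrient_cols = [c for c in table.columns if c != "energy_kcal"]
    for sid, row in table.iterrows():
        energy = float(row["energy_kcal"]) if "energy_kcal" in table.columns else None
        intakes = {c: float(row[c]) for c in nutrient_cols if pd.notna(row[c])}
        yield NutrientProfile(subject_id=sid, intakes=intakes, energy_kcal=energy, basis=basis)
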