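"""Reference database of global intake norms and inflammatory effect weights.

A :class:`ReferenceDatabase` holds, for each food parameter, the global mean
daily intake, its standard deviation, and the literature-derived inflammatory
effect score (negative = anti-inflammatory, positive = pro-inflammatory).
Two dialects exist: ``per_day`` (raw daily amounts) and ``per_1000kcal``
(nutrient densities, used for the energy-adjusted index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

from .errors import SchemaError, UsageError, ValidationError
from .vocabulary import PARAMETERS_45

DIALECTS = ("per_day", "per_1000kcal")

_REQUIRED_COLUMNS = ("name", "global_mean", "global_sd", "effect_score")


@dataclass(frozen=True)
class FoodParameterRef:
    """Reference entry for a single food parameter.

    ``global_mean``/``global_sd`` are in the parameter's intake units (per day
    or per 1000 kcal depending on the owning database's dialect);
    ``effect_score`` is the unitless inflammatory weight, |w| <= 1.
    """

    name: str
    global_mean: float
    global_sd: float
    effect_score: float

    def __post_init__(self):
        if not math.isfinite(self.global_mean):
            raise ValidationError(f"{self.name}: global_mean must be finite")
        if not (math.isfinite(self.global_sd) and self.global_sd > 0):
            raise ValidationError(f"{self.name}: global_sd must be > 0, got {self.global_sd!r}")
        if not (math.isfinite(self.effect_score) and abs(self.effect_score) <= 1):
            raise ValidationError(
                f"{self.name}: effect_score must satisfy |w| <= 1, got {self.effect_score!r}"
            )


class ReferenceDatabase:
    """Collection of :class:`FoodParameterRef` keyed by parameter name.

    Parameters
    ----------
    parameters
        The reference entries; names must be unique.
    dialect
        ``per_day`` or ``per_1000kcal``; declared explicitly, never inferred.
    strict_names
        If True (default), every name must belong to the canonical
        45-parameter vocabulary.
    """

    def __init__(self, parameters: Iterable[FoodParameterRef], dialect: str,
                 *, strict_names: bool = True):
        if dialect not in DIALECTS:
            raise UsageError(f"dialect must be one of {DIALECTS}, got {dialect!r}")
        self.dialect = dialect
        self._params: dict[str, FoodParameterRef] = {}
        for p in parameters:
            if p.name in self._params:
                raise ValidationError(f"duplicate parameter name: {p.name!r}")
            if strict_names and p.name not in PARAMETERS_45:
                raise ValidationError(f"unknown parameter name: {p.name!r}")
            self._params[p.name] = p
        if len(self._params) > 45:
            raise ValidationError("a reference database holds at most 45 parameters")

    # mapping-style access -------------------------------------------------
    def __len__(self) -> int:
        return len(self._params)

    def __iter__(self) -> Iterator[FoodParameterRef]:
        return iter(self._params.values())

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __getitem__(self, name: str) -> FoodParameterRef:
        return self._params[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._params)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [p.name for p in self],
                "global_mean": [p.global_mean for p in self],
                "global_sd": [p.global_sd for p in self],
                "effect_score": [p.effect_score for p in self],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dialect: str,
                   *, strict_names: bool = True) -> "ReferenceDatabase":
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"reference table is missing columns: {missing}")
        dupes = frame["name"][frame["name"].duplicated()].tolist()
        if dupes:
            raise ValidationError(f"duplicate parameter name: {dupes[0]!r}")
        params = [
            FoodParameterRef(
                name=str(r["name"]),
                global_mean=float(r["global_mean"]),
                global_sd=float(r["global_sd"]),
                effect_score=float(r["effect_score"]),
            )
            for _, r in frame.iterrows()
        ]
        return cls(params, dialect, strict_names=strict_names)


def load_reference(path, dialect: str, *, strict_names: bool = True) -> ReferenceDatabase:
    """Read a delimited reference table (comma or tab separated, header row).

    Required columns: ``name, global_mean, global_sd, effect_score``. The
    dialect is supplied by the caller, never guessed from the file.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    return ReferenceDatabase.from_frame(frame, dialect, strict_names=strict_names)


def save_reference(db: ReferenceDatabase, path) -> None:
    db.to_frame().to_csv(path, index=False)
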