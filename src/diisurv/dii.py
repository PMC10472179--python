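"""Dietary inflammatory index scoring.

The score for one subject is

    DII = sum_i  w_i * (2 * Phi((X_i - mu_i) / sigma_i) - 1)

where X_i is the subject's mean daily intake of food parameter i, mu_i and
sigma_i are the global reference mean and SD, w_i is the literature-derived
inflammatory effect weight, and Phi is the standard normal CDF. The centred
percentile 2*Phi(z) - 1 bounds each parameter's influence to (-1, 1), so each
component contribution is bounded by |w_i|.

The energy-adjusted variant scores nutrient densities X_i / (E / 1000 kcal)
against a per-1000 kcal reference database; the energy parameter itself is
dropped there (its density is identically 1000 kcal and carries no
information).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .errors import DomainError, UsageError, ValidationError
from .profiles import ENERGY, NutrientProfile
from .reference import FoodParameterRef, ReferenceDatabase

log = logging.getLogger(__name__)


def centered_percentile(z):
    """Map a standard score to the centred percentile 2*Phi(z) - 1 in (-1, 1).

    Odd-symmetric and strictly increasing; z = 0 maps to 0. Accepts scalars
    or arrays.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise DomainError("centered_percentile requires finite z")
    out = 2.0 * norm.cdf(z) - 1.0
    return float(out) if out.ndim == 0 else out


def component_score(intake: float, ref: FoodParameterRef) -> float:
    """One parameter's contribution: w * (2*Phi((X - mu)/sigma) - 1)."""
    if intake < 0 or not np.isfinite(intake):
        raise DomainError(f"{ref.name}: intake must be finite and >= 0")
    z = (intake - ref.global_mean) / ref.global_sd
    return ref.effect_score * centered_percentile(z)


@dataclass(frozen=True)
class DIIResult:
    """Total DII plus the per-parameter contributions that produced it."""

    subject_id: object
    total: float
    components: dict
    used_parameters: tuple
    skipped_parameters: tuple


def _resolve_params(params, db: ReferenceDatabase) -> tuple:
    if params is None:
        return db.names
    params = tuple(params)
    unknown = [p for p in params if p not in db]
    if unknown:
        raise UsageError(f"parameters not in reference database: {unknown}")
    return params


def dii_score(profile: NutrientProfile, db: ReferenceDatabase,
              params: Iterable[str] | None = None,
              *, min_coverage: int = 1) -> DIIResult:
    """Score one profile against a reference database.

    ``params`` defaults to every parameter in the database. Parameters
    requested but absent from the profile contribute nothing and are listed
    in ``skipped_parameters``; if fewer than ``min_coverage`` parameters are
    usable, a :class:`ValidationError` is raised instead.
    """
    if profile.basis != db.dialect:
        raise UsageError(
            f"profile basis {profile.basis!r} does not match database dialect {db.dialect!r}"
        )
    params = _resolve_params(params, db)
    used = tuple(p for p in params if p in profile.intakes)
    skipped = tuple(p for p in params if p not in profile.intakes)
    if len(used) == 0:
        raise ValidationError("no usable parameters: a DII over zero parameters is undefined")
    if len(used) < min_coverage:
        raise ValidationError(
            f"only {len(used)} of {len(params)} parameters usable "
            f"(min_coverage={min_coverage}); skipped: {skipped}"
        )
    x = np.array([profile.intakes[p] for p in used], dtype=float)
    mu = np.array([db[p].global_mean for p in used])
    sd = np.array([db[p].global_sd for p in used])
    w = np.array([db[p].effect_score for p in used])
    contrib = w * centered_percentile((x - mu) / sd)
    components = dict(zip(used, contrib.tolist()))
    return DIIResult(
        subject_id=profile.subject_id,
        total=float(contrib.sum()),
        components=components,
        used_parameters=used,
        skipped_parameters=skipped,
    )


def energy_adjusted_dii(profile: NutrientProfile, db_density: ReferenceDatabase,
                        params: Iterable[str] | None = None,
                        *, min_coverage: int = 1) -> DIIResult:
    """Energy-adjusted DII via the density method.

    Each per-day intake is converted to an amount per 1000 kcal
    (X_i / (E/1000)) and scored against a per-1000 kcal reference database.
    The result is invariant under proportional scaling of all intakes and
    energy. The energy parameter is excluded: its density is the constant
    1000 kcal per 1000 kcal.
    """
    if db_density.dialect != "per_1000kcal":
        raise UsageError("energy_adjusted_dii needs a per_1000kcal reference database")
    if profile.basis != "per_day":
        raise UsageError("energy_adjusted_dii needs a per_day profile")
    if profile.energy_kcal is None or profile.energy_kcal <= 0:
        raise DomainError("energy_kcal must be > 0 for energy adjustment")
    params = _resolve_params(params, db_density)
    if ENERGY in params:
        log.info("dropping 'energy' from the energy-adjusted parameter set (density is constant)")
        params = tuple(p for p in params if p != ENERGY)
    factor = profile.energy_kcal / 1000.0
    dens = {p: x / factor for p, x in profile.intakes.items() if p != ENERGY}
    dens_profile = NutrientProfile(
        subject_id=profile.subject_id, intakes=dens, energy_kcal=None, basis="per_1000kcal"
    )
    return dii_score(dens_profile, db_density, params, min_coverage=min_coverage)


def score_profiles(intakes, db: ReferenceDatabase,
                   params: Sequence[str] | None = None,
                   *, energy_kcal=None, energy_adjusted: bool = False):
    """Vectorised scoring of many subjects at once.

    Parameters
    ----------
    intakes
        DataFrame, one row per subject, nutrient columns in the per-day basis
        (or already in densities if ``energy_adjusted`` is False and the
        database dialect is per_1000kcal — the caller is responsible for
        basis consistency, as with :func:`dii_score`).
    db
        Reference database; its dialect must match the basis being scored.
    params
        Parameter subset; defaults to database ∩ columns.
    energy_kcal
        Series aligned with ``intakes`` (or the name of a column) giving
        daily energy; required when ``energy_adjusted``.
    energy_adjusted
        If True, convert intakes to per-1000 kcal densities first and drop
        the energy parameter.

    Returns
    -------
    DataFrame indexed like ``intakes`` with a ``dii_total`` column and one
    ``component_<name>`` column per scored parameter.
    """
    import pandas as pd

    if params is None:
        params = [p for p in db.names if p in intakes.columns]
    else:
        params = [p for p in params]
        missing = [p for p in params if p not in intakes.columns]
        if missing:
            raise UsageError(f"intake table lacks columns for parameters: {missing}")
        unknown = [p for p in params if p not in db]
        if unknown:
            raise UsageError(f"parameters not in reference database: {unknown}")

    x = intakes[params].to_numpy(dtype=float) if params else np.empty((len(intakes), 0))
    if energy_adjusted:
        if db.dialect != "per_1000kcal":
            raise UsageError("energy-adjusted scoring needs a per_1000kcal database")
        if isinstance(energy_kcal, str):
            energy_kcal = intakes[energy_kcal]
        if energy_kcal is None:
            raise UsageError("energy_kcal is required for energy-adjusted scoring")
        e = np.asarray(energy_kcal, dtype=float)
        if np.any(~np.isfinite(e)) or np.any(e <= 0):
            raise DomainError("energy_kcal must be finite and > 0 for every subject")
        if ENERGY in params:
            keep = [i for i, p in enumerate(params) if p != ENERGY]
            x = x[:, keep]
            params = [p for p in params if p != ENERGY]
        x = x / (e[:, None] / 1000.0)
    if not params:
        raise ValidationError("no usable parameters: a DII over zero parameters is undefined")

    mu = np.array([db[p].global_mean for p in params])
    sd = np.array([db[p].global_sd for p in params])
    w = np.array([db[p].effect_score for p in params])
    contrib = w * (2.0 * norm.cdf((x - mu) / sd) - 1.0)
    out = pd.DataFrame(contrib, index=intakes.index,
                       columns=[f"component_{p}" for p in params])
    out.insert(0, "dii_total", contrib.sum(axis=1))
    return out
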