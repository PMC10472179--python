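import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from diisurv import (FoodParameterRef, ModelSpec, NutrientProfile,
                     ReferenceDatabase, ScenarioConfig, run_scenario)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# --------------------------------------------------------------------------
# independent scalar oracles (pure python / math module, no package code)
# --------------------------------------------------------------------------

def phi(z: float) -> float:
    """Standard normal CDF via the error function."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def brute_force_dii(intakes: dict, db, params) -> tuple[float, dict]:
    """Loop-based DII: z-score, centred percentile, weight, sum."""
    total = 0.0
    comps = {}
    for p in params:
        if p not in intakes:
            continue
        ref = db[p]
        z = (intakes[p] - ref.global_mean) / ref.global_sd
        c = ref.effect_score * (2.0 * phi(z) - 1.0)
        comps[p] = c
        total += c
    return total, comps


def brute_force_quintiles(values, n_groups: int = 5) -> list:
    """Sort-and-slice quintiles, ties take the first occurrence's block."""
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    block_of_value = {}
    for pos, i in enumerate(order):
        b = (pos * n_groups) // n
        v = values[i]
        if v not in block_of_value:
            block_of_value[v] = b
    return [block_of_value[v] + 1 for v in values]


def natural_spline_scalar(x: float, knots) -> list:
    """Truncated-power natural cubic spline basis at one point."""
    k = len(knots)
    norm = (knots[-1] - knots[0]) ** 2
    out = [x]
    for j in range(k - 2):
        def plus3(u):
            return max(u, 0.0) ** 3
        term = (
            plus3(x - knots[j])
            - plus3(x - knots[-2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + plus3(x - knots[-1]) * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        ) / norm
        out.append(term)
    return out


def random_reference(rng, n_params=10, dialect="per_day"):
    from diisurv.vocabulary import PARAMETERS_45

    names = rng.choice(np.array(PARAMETERS_45, dtype=object), size=n_params,
                       replace=False)
    params = [
        FoodParameterRef(
            name=str(nm),
            global_mean=float(rng.uniform(1, 200)),
            global_sd=float(rng.uniform(0.5, 60)),
            effect_score=float(rng.uniform(-1, 1)),
        )
        for nm in names
    ]
    return ReferenceDatabase(params, dialect)


def random_profile(rng, db, subject_id=0):
    intakes = {p.name: float(rng.uniform(0, 2.5 * p.global_mean)) for p in db}
    return NutrientProfile(subject_id=subject_id, intakes=intakes,
                           energy_kcal=float(rng.uniform(800, 4000)),
                           basis=db.dialect if db.dialect == "per_day" else "per_1000kcal")


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tiny_reference():
    """Three-parameter per-day database with round numbers."""
    return ReferenceDatabase(
        [
            FoodParameterRef("fiber", 18.0, 4.0, -0.66),
            FoodParameterRef("saturated_fat", 28.0, 8.0, 0.37),
            FoodParameterRef("vitamin_c", 118.0, 43.0, -0.42),
        ],
        "per_day",
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """One moderately sized simulated cohort with a real DII effect,
    shared across survival-stage tests."""
    cfg = ScenarioConfig(n_subjects=2000)
    cohort, truth, log = run_scenario(cfg, seed=20200)
    return cohort


@pytest.fixture(scope="session")
def women_cohort(sim_cohort):
    return sim_cohort[sim_cohort["sex"] == "woman"]
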