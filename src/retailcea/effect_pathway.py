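"""Intervention-effect pathway: purchases -> energy -> weight -> BMI.

The policy's effect on purchases of restricted products is combined from
trial/natural-experiment effect sizes, scaled by market coverage, and
converted first to a daily energy-intake reduction per age/sex stratum, then
to a steady-state body-weight change, and finally to a BMI change using
stratum mean height. The pathway assumes the proportional purchase reduction
translates one-for-one into consumption with no compensatory intake of
non-restricted products, and reports equilibrium (not dynamic) weight change.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    RESTRICTED_CATEGORIES,
    ConfigurationError,
    CoverageFactors,
    EffectEstimate,
)

#: Steady-state energy-balance constants (kJ/day of sustained intake change
#: per kg of equilibrium body-weight change).
ADULT_KJ_PER_KG = 94.0
CHILD_KJ_PER_KG = 100.0
ADULT_AGE = 18


def piernas_effect(control_increase: float = 0.31, intervention_increase: float = 0.12,
                   method: str = "difference") -> float:
    """Operationalise an arm-contrast purchase effect.

    Default is the arithmetic difference of arm-level proportional increases
    (0.31 - 0.12 = 0.19); ``method="ratio"`` gives 1 - (1 + i)/(1 + c).
    """
    if method == "difference":
        return control_increase - intervention_increase
    if method == "ratio":
        return 1.0 - (1.0 + intervention_increase) / (1.0 + control_increase)
    raise ConfigurationError(f"unknown effect method {method!r}")


def combine_effect_sizes(study_effects: Sequence[float]) -> EffectEstimate:
    """Unweighted mean of per-study proportional purchase reductions.

    Each effect must be a fraction in [0, 1]; the default two-study inputs
    (0.155 and 0.31 - 0.12 = 0.19) combine to 0.1725.
    """
    effects = list(study_effects)
    if not effects:
        raise ValueError("no study effects supplied")
    for e in effects:
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"study effect {e} outside [0, 1]")
    return EffectEstimate(point=float(np.mean(effects)))


def energy_reduction(
    intake: pd.DataFrame,
    factors: CoverageFactors,
    effect: EffectEstimate,
    categories: Iterable[str] = RESTRICTED_CATEGORIES,
) -> pd.Series:
    """Daily energy reduction (kJ/day, <= 0) per (age, sex) stratum.

    delta_kj = -sum over categories of
        intake * market_share * supermarket_purchase_share * effect.

    ``categories`` restricts which product groups the policy binds (the
    chocolate-only scenario passes a single category). No compensatory
    consumption term is applied.
    """
    categories = list(categories)
    unknown = set(categories) - set(RESTRICTED_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    sub = intake[intake["category"].isin(categories)]
    total = sub.groupby(["age", "sex"])["kj_per_day"].sum()
    # strata with no selected-category rows contribute zero
    all_strata = intake.groupby(["age", "sex"]).size().index
    total = total.reindex(all_strata, fill_value=0.0)
    scale = factors.market_share * factors.supermarket_purchase_share * effect.point
    return (-total * scale).rename("delta_kj")


def energy_to_weight(
    delta_kj,
    age,
    adult_kj_per_kg: float = ADULT_KJ_PER_KG,
    child_kj_per_kg: float = CHILD_KJ_PER_KG,
    adult_age: int = ADULT_AGE,
):
    """Steady-state weight change (kg) from a sustained kJ/day change.

    delta_weight = delta_kj / coefficient, where the coefficient is the
    adult constant for ages >= ``adult_age`` and the child constant below.
    Sign is preserved. Accepts scalars or aligned arrays.
    """
    if adult_kj_per_kg <= 0 or child_kj_per_kg <= 0:
        raise ConfigurationError("energy-to-weight coefficients must be positive")
    coeff = np.where(np.asarray(age) >= adult_age, adult_kj_per_kg, child_kj_per_kg)
    out = np.asarray(delta_kj, dtype=float) / coeff
    return float(out) if out.ndim == 0 else out


def weight_to_bmi(delta_weight, height):
    """BMI change (kg/m^2) = weight change / height^2."""
    h = np.asarray(height, dtype=float)
    if np.any(h <= 0):
        raise ValueError("height must be positive")
    out = np.asarray(delta_weight, dtype=float) / h**2
    return float(out) if out.ndim == 0 else out


def body_impact(
    population: pd.DataFrame,
    intake: pd.DataFrame,
    factors: CoverageFactors,
    effect: EffectEstimate,
    categories: Iterable[str] = RESTRICTED_CATEGORIES,
    adult_kj_per_kg: float = ADULT_KJ_PER_KG,
    child_kj_per_kg: float = CHILD_KJ_PER_KG,
) -> pd.DataFrame:
    """Full pathway per population stratum.

    Returns a frame with age, sex, delta_kj, delta_weight, delta_bmi (all
    <= 0 for a purchase-reducing policy). Strata are the population rows;
    intake is looked up at the stratum's age (for a collapsed small-scale
    population, at its representative age).
    """
    dkj = energy_reduction(intake, factors, effect, categories)
    pop = population.copy()
    key = list(zip(pop["age"].astype(int), pop["sex"]))
    pop["delta_kj"] = [float(dkj.get(k, 0.0)) for k in key]
    pop["delta_weight"] = energy_to_weight(
        pop["delta_kj"].to_numpy(), pop["age"].to_numpy(),
        adult_kj_per_kg=adult_kj_per_kg, child_kj_per_kg=child_kj_per_kg,
    )
    pop["delta_bmi"] = weight_to_bmi(pop["delta_weight"].to_numpy(), pop["mean_height"].to_numpy())
    return pop[["age", "sex", "count", "mean_height", "delta_kj", "delta_weight", "delta_bmi"]]


def population_means(impact: pd.DataFrame) -> pd.DataFrame:
    """Count-weighted mean delta_kj / delta_weight / delta_bmi by sex."""
    rows = []
    for sex, sub in impact.groupby("sex"):
        w = sub["count"].to_numpy()
        rows.append(
            {
                "sex": sex,
                "mean_delta_kj": float(np.average(sub["delta_kj"], weights=w)),
                "mean_delta_weight": float(np.average(sub["delta_weight"], weights=w)),
                "mean_delta_bmi": float(np.average(sub["delta_bmi"], weights=w)),
            }
        )
    return pd.DataFrame(rows)
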