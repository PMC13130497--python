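"""Synthetic model inputs.

Generates an internally consistent bundle of inputs for the whole pipeline:
a population with anthropometry, daily energy intake from the four restricted
discretionary categories, epidemiology for the nine obesity-related diseases,
an all-cause life table with background morbidity, loaded-wage inputs and the
fixed policy-cost parameters. Magnitudes are plausible for a high-income
population of ~26 million but are not estimates of any real country's data.

Calibration: restricted-category intake is scaled so the population-weighted
mean totals are 772 kJ/day (males) and 521 kJ/day (females), the levels at
which the effect pathway produces mean daily energy reductions of roughly
83 kJ (males) and 56 kJ (females) under the default coverage and effect size.

Randomness uses one master seed with independent sub-streams per data domain,
so regenerating one domain never perturbs another.
"""
from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AGE_MAX,
    AGE_MIN,
    AGES,
    DISEASES,
    FEMALE_ONLY_DISEASES,
    OCCUPATIONS,
    RESTRICTED_CATEGORIES,
    SEXES,
    ConfigurationError,
    DiseaseSpec,
    InputBundle,
    ValidationError,
)

#: Representative ages used by the collapsed ("small") population, one per
#: 5-year band starting at age 2.
SMALL_SCALE_AGES = tuple(range(AGE_MIN, AGE_MAX + 1, 5))

#: Calibration targets for population-mean restricted-category intake (kJ/day).
INTAKE_TARGET = {"male": 772.0, "female": 521.0}

_CATEGORY_SHARES = {
    "chocolate_confectionery": 0.30,
    "puddings_biscuits": 0.28,
    "savoury_snacks": 0.17,
    "sugary_beverages": 0.25,
}

# Disease catalogue: incidence follows a logistic age curve
# inc_max / (1 + exp(-(age - mid) / slope)) from min_age, with a female
# multiplier; prevalence ~ incidence x mean duration (capped); case fatality
# carries a mild age gradient. Magnitudes loosely follow published
# high-income-country burden patterns without claiming accuracy.
_DISEASE_PARAMS: Mapping[str, dict] = {
    "ischaemic_heart_disease": dict(inc=0.0120, mid=72, slope=9, f=0.60, dur=10, cf=0.040, rem=0.00, dw=0.080, cost=8000.0, rr=1.15),
    "hypertensive_heart_disease": dict(inc=0.0025, mid=75, slope=8, f=0.90, dur=8, cf=0.060, rem=0.00, dw=0.100, cost=6000.0, rr=1.25),
    "ischaemic_stroke": dict(inc=0.0080, mid=76, slope=8, f=0.85, dur=7, cf=0.080, rem=0.00, dw=0.320, cost=9000.0, rr=1.10),
    "diabetes": dict(inc=0.0090, mid=60, slope=12, f=0.90, dur=25, cf=0.010, rem=0.00, dw=0.049, cost=4500.0, rr=1.25),
    "colorectal_cancer": dict(inc=0.0025, mid=72, slope=9, f=0.80, dur=5, cf=0.100, rem=0.05, dw=0.210, cost=15000.0, rr=1.05),
    "kidney_cancer": dict(inc=0.0006, mid=68, slope=10, f=0.60, dur=5, cf=0.120, rem=0.05, dw=0.210, cost=16000.0, rr=1.08),
    "breast_cancer": dict(inc=0.0028, mid=62, slope=14, f=1.00, dur=8, cf=0.040, rem=0.06, dw=0.200, cost=14000.0, rr=1.05),
    "endometrial_cancer": dict(inc=0.0008, mid=64, slope=9, f=1.00, dur=6, cf=0.050, rem=0.06, dw=0.200, cost=13000.0, rr=1.18),
    "osteoarthritis": dict(inc=0.0100, mid=65, slope=11, f=1.30, dur=30, cf=0.000, rem=0.00, dw=0.130, cost=3000.0, rr=1.10),
}

_BASE_WAGES = {
    "general_manager": 80.0,
    "retail_manager": 45.0,
    "stock_control_clerk": 35.0,
    "sales_assistant": 30.0,
    "government_officer": 52.0,
}

_PREVALENCE_CAP = 0.30


def default_cost_config() -> dict:
    """Fixed policy-cost parameters (A$ 2024) used by the costing module."""
    return {
        "chains": 4,
        "stores": 4105,
        "products_per_chain": 25000,
        "new_products_per_chain_per_year": 1000,
        "food_share": 0.79,
        "assessment_minutes": [5.0, 10.0],
        "head_office_hours": 12.0,
        "familiarisation": {"manager_hours": 3.0, "clerk_hours": 3.0, "clerks": 2},
        "layout": {
            "day_hours": 7.6,
            "manager_days": 1.0,
            "clerk_days": 1.0,
            "assistants": 4,
            "assistant_days": 1.5,
        },
        "monitoring": {
            "check_fraction": 0.07,
            "years": 3,
            "unit_cost": 850.0,
            "noncompliance": [0.30, 0.20, 0.10],
            "penalty": 5500.0,
        },
        "fixed": {
            "legislation": 1_560_000.0,
            "media": 960_000.0,
            "complaints_annual": 57_000.0,
        },
        "cpi": {2019: 114.8, 2020: 116.6, 2021: 119.7, 2022: 127.3, 2023: 134.2, 2024: 138.8},
        "base_year": 2024,
    }


def _age_array() -> np.ndarray:
    return np.asarray(AGES, dtype=float)


def _population_counts(rng: np.random.Generator) -> dict:
    """Per-sex counts by single year of age; smooth pyramid with mild noise."""
    a = _age_array()
    base = 160_000.0 / (1.0 + np.exp((a - 80.0) / 7.0))
    out = {}
    for sex in SEXES:
        noise = rng.lognormal(mean=0.0, sigma=0.02, size=a.size)
        out[sex] = base * noise
    return out


def _mean_bmi(a: np.ndarray, sex: str) -> np.ndarray:
    child = 15.8 + 0.42 * (a - 2.0)
    adult = 23.0 + 4.8 * (1.0 - np.exp(-(a - 18.0) / 22.0)) - 0.025 * np.clip(a - 72.0, 0.0, None)
    bmi = np.where(a < 18, child, adult)
    if sex == "female":
        bmi = bmi - 0.3 * (a >= 18)
    return np.clip(bmi, 12.5, 44.0)


def _sd_bmi(a: np.ndarray) -> np.ndarray:
    return 2.0 + 3.0 / (1.0 + np.exp(-(a - 18.0) / 4.0))


def _mean_height(a: np.ndarray, sex: str) -> np.ndarray:
    h_adult = 1.78 if sex == "male" else 1.645
    h = h_adult - (h_adult - 0.87) * np.exp(-0.16 * (a - 2.0))
    return h - 0.0006 * np.clip(a - 60.0, 0.0, None)


def _intake_shape(a: np.ndarray) -> np.ndarray:
    # Relative intake by age: peaks in adolescence/young adulthood.
    return 0.35 + 0.65 * np.exp(-0.5 * ((a - 20.0) / 18.0) ** 2)


def generate_population(rng: np.random.Generator) -> pd.DataFrame:
    a = _age_array()
    counts = _population_counts(rng)
    rows = []
    for sex in SEXES:
        rows.append(
            pd.DataFrame(
                {
                    "age": a.astype(int),
                    "sex": sex,
                    "count": counts[sex],
                    "mean_bmi": _mean_bmi(a, sex),
                    "sd_bmi": _sd_bmi(a),
                    "mean_height": _mean_height(a, sex),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_intake(rng: np.random.Generator, population: pd.DataFrame) -> pd.DataFrame:
    """Category intake by age/sex, calibrated to the population-mean targets."""
    a = _age_array()
    shape = _intake_shape(a)
    rows = []
    for sex in SEXES:
        pop = population[population["sex"] == sex].set_index("age")["count"].reindex(AGES)
        weights = pop.to_numpy() / pop.to_numpy().sum()
        for cat in RESTRICTED_CATEGORIES:
            noise = rng.lognormal(mean=0.0, sigma=0.06, size=a.size)
            raw = shape * _CATEGORY_SHARES[cat] * noise
            rows.append(
                pd.DataFrame({"age": a.astype(int), "sex": sex, "category": cat, "kj_per_day": raw})
            )
        # rescale this sex's four categories jointly to hit the mean target
        block = pd.concat(rows[-4:], ignore_index=True)
        total_by_age = block.groupby("age")["kj_per_day"].sum().reindex(AGES).to_numpy()
        current_mean = float(np.sum(weights * total_by_age))
        factor = INTAKE_TARGET[sex] / current_mean
        for df in rows[-4:]:
            df["kj_per_day"] *= factor
    return pd.concat(rows, ignore_index=True)


def generate_diseases(min_age: int = 20) -> dict:
    """The nine-disease catalogue as smooth logistic age curves."""
    a = _age_array()
    out = {}
    for name in DISEASES:
        p = _DISEASE_PARAMS[name]
        frames = []
        for sex in SEXES:
            if name in FEMALE_ONLY_DISEASES and sex == "male":
                inc = np.zeros_like(a)
            else:
                mult = p["f"] if sex == "female" else 1.0
                inc = mult * p["inc"] / (1.0 + np.exp(-(a - p["mid"]) / p["slope"]))
                inc = np.where(a < min_age, 0.0, inc)
            prev = np.clip(inc * p["dur"], 0.0, _PREVALENCE_CAP)
            cf = p["cf"] * (0.5 + a / 100.0)
            frames.append(
                pd.DataFrame(
                    {
                        "age": a.astype(int),
                        "sex": sex,
                        "incidence": inc,
                        "prevalence": prev,
                        "case_fatality": cf,
                        "remission": np.full_like(a, p["rem"]),
                        "disability_weight": np.full_like(a, p["dw"]),
                        "annual_cost_per_case": np.full_like(a, p["cost"]),
                        "rr_per_bmi_unit": np.full_like(a, p["rr"]),
                        "min_age": min_age,
                    }
                )
            )
        out[name] = DiseaseSpec(name=name, table=pd.concat(frames, ignore_index=True), min_age=min_age)
    return out


def generate_lifetable() -> pd.DataFrame:
    a = _age_array()
    rows = []
    for sex in SEXES:
        mult = 0.82 if sex == "female" else 1.0
        acm = mult * (0.00030 + 2.0e-5 * np.exp(0.094 * a)) + 0.0003 * np.exp(-(a - 2.0) / 4.0)
        acm = np.clip(acm, 0.0, 0.95)
        pyld = 0.015 + 0.22 / (1.0 + np.exp(-(a - 72.0) / 11.0))
        rows.append(
            pd.DataFrame(
                {"age": a.astype(int), "sex": sex, "all_cause_mortality": acm, "background_pyld": pyld}
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_wages() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "occupation": list(OCCUPATIONS),
            "base_hourly_wage": [_BASE_WAGES[o] for o in OCCUPATIONS],
            "on_cost_rate": 0.13,
            "leave_loading_rate": 0.175,
        }
    )


def collapse_population(population: pd.DataFrame) -> pd.DataFrame:
    """Collapse single-year ages to 5-year-band representative ages.

    Band counts are summed onto the band's first age; anthropometry is the
    count-weighted band mean. Used by the ``small`` scale for fast tests.
    """
    out = []
    for sex in SEXES:
        sub = population[population["sex"] == sex].set_index("age")
        for rep in SMALL_SCALE_AGES:
            band = sub.loc[[x for x in range(rep, min(rep + 5, AGE_MAX + 1)) if x in sub.index]]
            w = band["count"].to_numpy()
            out.append(
                {
                    "age": rep,
                    "sex": sex,
                    "count": float(w.sum()),
                    "mean_bmi": float(np.average(band["mean_bmi"], weights=w)),
                    "sd_bmi": float(np.average(band["sd_bmi"], weights=w)),
                    "mean_height": float(np.average(band["mean_height"], weights=w)),
                }
            )
    return pd.DataFrame(out)


def generate_all(seed: int, scale: str = "full", out_dir: str | None = None) -> InputBundle:
    """Generate the full input bundle; optionally write it to ``out_dir``.

    ``scale="small"`` collapses the population to 5-year-band representative
    ages (rate tables stay at single-year resolution because cohorts age
    through every year). Deterministic for a fixed seed.
    """
    if scale not in ("small", "full"):
        raise ConfigurationError(f"unknown scale {scale!r}; expected 'small' or 'full'")
    ss = np.random.SeedSequence(seed)
    rng_pop, rng_intake, rng_epi, rng_wage = (np.random.default_rng(s) for s in ss.spawn(4))
    population = generate_population(rng_pop)
    intake = generate_intake(rng_intake, population)
    diseases = generate_diseases()
    lifetable = generate_lifetable()
    wages = generate_wages()
    cost_config = default_cost_config()
    cost_config["scale"] = scale
    if scale == "small":
        population = collapse_population(population)
    bundle = InputBundle(
        population=population,
        intake=intake,
        diseases=diseases,
        lifetable=lifetable,
        wages=wages,
        cost_config=cost_config,
        scale=scale,
    )
    if out_dir is not None:
        write_inputs(bundle, out_dir)
    return bundle


_FLOAT_FMT = "%.12g"


def write_inputs(bundle: InputBundle, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "diseases"), exist_ok=True)
    bundle.population.to_csv(os.path.join(out_dir, "population.csv"), index=False, float_format=_FLOAT_FMT)
    bundle.intake.to_csv(os.path.join(out_dir, "intake.csv"), index=False, float_format=_FLOAT_FMT)
    bundle.lifetable.to_csv(os.path.join(out_dir, "lifetable.csv"), index=False, float_format=_FLOAT_FMT)
    bundle.wages.to_csv(os.path.join(out_dir, "wages.csv"), index=False, float_format=_FLOAT_FMT)
    for name, spec in bundle.diseases.items():
        spec.table.to_csv(os.path.join(out_dir, "diseases", f"{name}.csv"), index=False, float_format=_FLOAT_FMT)
    with open(os.path.join(out_dir, "cost_inputs.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle.cost_config, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------


def _check_age_coverage(df: pd.DataFrame, label: str, ages: Iterable[int]) -> list:
    problems = []
    want = set(ages)
    for sex in SEXES:
        have = set(df.loc[df["sex"] == sex, "age"].astype(int))
        missing = sorted(want - have)
        if missing:
            problems.append(f"{label}: incomplete age coverage for {sex} (missing ages {missing[:8]}{'...' if len(missing) > 8 else ''})")
        extra = sorted(have - want)
        if extra:
            problems.append(f"{label}: unexpected ages for {sex}: {extra[:8]}")
    return problems


def _check_range(df: pd.DataFrame, label: str, col: str, lo=None, hi=None,
                 lo_strict=False, hi_strict=False) -> list:
    problems = []
    v = df[col]
    bad = pd.Series(False, index=df.index)
    if lo is not None:
        bad |= (v <= lo) if lo_strict else (v < lo)
    if hi is not None:
        bad |= (v >= hi) if hi_strict else (v > hi)
    for _, row in df[bad].head(10).iterrows():
        where = ", ".join(f"{k}={row[k]}" for k in ("age", "sex", "category") if k in df.columns)
        problems.append(f"{label}: {col}={row[col]} out of range at ({where})")
    return problems


def validate_bundle(bundle: InputBundle) -> None:
    """Check every structural and range invariant; raise with row identifiers."""
    problems: list = []
    pop_ages = SMALL_SCALE_AGES if bundle.scale == "small" else AGES
    problems += _check_age_coverage(bundle.population, "population", pop_ages)
    problems += _check_range(bundle.population, "population", "count", lo=0, lo_strict=True)
    problems += _check_range(bundle.population, "population", "sd_bmi", lo=0, lo_strict=True)
    problems += _check_range(bundle.population, "population", "mean_height", lo=0, lo_strict=True)
    problems += _check_range(bundle.population, "population", "mean_bmi", lo=12, hi=45)

    have_cats = set(bundle.intake["category"])
    if have_cats != set(RESTRICTED_CATEGORIES):
        problems.append(f"intake: category set {sorted(have_cats)} != restricted list")
    for cat in set(RESTRICTED_CATEGORIES) & have_cats:
        sub = bundle.intake[bundle.intake["category"] == cat]
        problems += _check_age_coverage(sub, f"intake[{cat}]", AGES)
    problems += _check_range(bundle.intake, "intake", "kj_per_day", lo=0)

    problems += _check_age_coverage(bundle.lifetable, "lifetable", AGES)
    problems += _check_range(bundle.lifetable, "lifetable", "all_cause_mortality", lo=0, hi=1, hi_strict=True)
    problems += _check_range(bundle.lifetable, "lifetable", "background_pyld", lo=0, hi=1, hi_strict=True)

    if set(bundle.diseases) != set(DISEASES):
        problems.append(f"diseases: catalogue {sorted(bundle.diseases)} != nine-disease list")
    for name, spec in bundle.diseases.items():
        t = spec.table
        problems += _check_age_coverage(t, f"disease[{name}]", AGES)
        for col in ("incidence", "case_fatality", "remission"):
            problems += _check_range(t, f"disease[{name}]", col, lo=0)
        problems += _check_range(t, f"disease[{name}]", "prevalence", lo=0, hi=1, hi_strict=True)
        problems += _check_range(t, f"disease[{name}]", "disability_weight", lo=0, hi=1)
        problems += _check_range(t, f"disease[{name}]", "annual_cost_per_case", lo=0)
        problems += _check_range(t, f"disease[{name}]", "rr_per_bmi_unit", lo=0)

    if (bundle.wages["base_hourly_wage"] <= 0).any():
        problems.append("wages: non-positive base wage")
    missing_occ = set(OCCUPATIONS) - set(bundle.wages["occupation"])
    if missing_occ:
        problems.append(f"wages: missing occupations {sorted(missing_occ)}")

    if problems:
        raise ValidationError("; ".join(problems))


def load_inputs(in_dir: str) -> InputBundle:
    """Load a written bundle from ``in_dir`` and validate every invariant."""
    def p(name: str) -> str:
        path = os.path.join(in_dir, name)
        if not os.path.exists(path):
            raise ValidationError(f"missing input file {name}")
        return path

    population = pd.read_csv(p("population.csv"))
    intake = pd.read_csv(p("intake.csv"))
    lifetable = pd.read_csv(p("lifetable.csv"))
    wages = pd.read_csv(p("wages.csv"))
    with open(p("cost_inputs.yaml"), encoding="utf-8") as fh:
        cost_config = yaml.safe_load(fh)
    diseases = {}
    for name in DISEASES:
        t = pd.read_csv(p(os.path.join("diseases", f"{name}.csv")))
        diseases[name] = DiseaseSpec(name=name, table=t, min_age=int(t["min_age"].iloc[0]))
    bundle = InputBundle(
        population=population,
        intake=intake,
        diseases=diseases,
        lifetable=lifetable,
        wages=wages,
        cost_config=cost_config,
        scale=cost_config.get("scale", "full"),
    )
    validate_bundle(bundle)
    return bundle
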