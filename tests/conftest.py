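"""Shared fixtures: synthetic bundles, a toy bundle, and a naive model oracle.

The naive oracle re-implements the cohort life-table dynamics as plain
per-person-year Python loops (scalar arithmetic, explicit state variables),
independent of the vectorised engine. It shares only the public
``compute_pif`` function, which has its own independent checks (discrete
hand calculation, quadrature cross-check).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import retailcea.synthetic_data as sdata
from retailcea.config import RunConfig
from retailcea.pmslt import compute_pif
from retailcea.types import AGES, DiseaseSpec, InputBundle


@pytest.fixture(scope="session")
def bundle_small():
    return sdata.generate_all(1, scale="small")


@pytest.fixture(scope="session")
def bundle_full():
    return sdata.generate_all(1, scale="full")


@pytest.fixture(scope="session")
def config_small():
    return RunConfig(seed=1, scale="small")


def _toy_disease(name, inc0, inc_slope, cf, rem, dw, cost, rr, min_age=20):
    ages = np.asarray(AGES, float)
    frames = []
    for sex in ("male", "female"):
        mult = 1.0 if sex == "male" else 0.8
        inc = np.where(ages >= min_age, mult * (inc0 + inc_slope * ages), 0.0)
        frames.append(pd.DataFrame({
            "age": ages.astype(int), "sex": sex,
            "incidence": inc,
            "prevalence": np.clip(inc * 8.0, 0.0, 0.3),
            "case_fatality": np.full_like(ages, cf),
            "remission": np.full_like(ages, rem),
            "disability_weight": np.full_like(ages, dw),
            "annual_cost_per_case": np.full_like(ages, cost),
            "rr_per_bmi_unit": np.full_like(ages, rr),
            "min_age": min_age,
        }))
    return DiseaseSpec(name=name, table=pd.concat(frames, ignore_index=True), min_age=min_age)


@pytest.fixture(scope="session")
def toy_bundle():
    """3 diseases, 10 starting ages per sex; full-age rate tables."""
    ages = np.asarray(AGES, float)
    start_ages = list(range(55, 65))
    pop = []
    for sex in ("male", "female"):
        for a in start_ages:
            pop.append({"age": a, "sex": sex, "count": 1000.0,
                        "mean_bmi": 27.0 + 0.01 * a, "sd_bmi": 4.0,
                        "mean_height": 1.70})
    lifetable = []
    for sex in ("male", "female"):
        m = 1.0 if sex == "male" else 0.9
        lifetable.append(pd.DataFrame({
            "age": ages.astype(int), "sex": sex,
            "all_cause_mortality": np.clip(m * (0.005 + 0.0008 * (ages - 2.0)), 0, 0.9),
            "background_pyld": np.full_like(ages, 0.05),
        }))
    diseases = {
        "ischaemic_heart_disease": _toy_disease("ischaemic_heart_disease", 0.001, 1e-4, 0.05, 0.0, 0.10, 8000.0, 1.20),
        "diabetes": _toy_disease("diabetes", 0.004, 5e-5, 0.01, 0.0, 0.05, 4000.0, 1.25),
        "colorectal_cancer": _toy_disease("colorectal_cancer", 0.0005, 2e-5, 0.10, 0.04, 0.20, 15000.0, 1.06),
    }
    intake = pd.DataFrame({"age": [55], "sex": ["male"],
                           "category": ["chocolate_confectionery"], "kj_per_day": [0.0]})
    return InputBundle(
        population=pd.DataFrame(pop), intake=intake, diseases=diseases,
        lifetable=pd.concat(lifetable, ignore_index=True),
        wages=sdata.generate_wages(), cost_config=sdata.default_cost_config(),
        scale="small")


def naive_population_run(bundle, impact, discount_rate, horizon_years=None,
                         tmred=21.0, bmi_form="lognormal"):
    """Naive per-year cohort loop: the independent oracle for the engine.

    Returns total incremental HALYs and healthcare cost plus per-cohort
    streams, computed with scalar Python arithmetic.
    """
    names = list(bundle.diseases)
    lt = {sex: bundle.lifetable[bundle.lifetable["sex"] == sex].set_index("age")
          for sex in ("male", "female")}
    dis = {}
    for n in names:
        t = bundle.diseases[n].table
        dis[n] = {sex: t[t["sex"] == sex].set_index("age") for sex in ("male", "female")}
    pop_bmi = {sex: bundle.population[bundle.population["sex"] == sex].set_index("age")
               for sex in ("male", "female")}
    imp = impact.set_index(["age", "sex"])["delta_bmi"]

    lifetime = 100 - 2 + 1
    T_global = lifetime if horizon_years is None else min(horizon_years, lifetime)
    total_h, total_c = 0.0, 0.0
    per_cohort = []
    for _, row in bundle.population.iterrows():
        sex, a0, w = row["sex"], int(row["age"]), float(row["count"])
        delta = float(imp.loc[(a0, sex)])
        results = {}
        p_base = None
        for arm in ("baseline", "intervention"):
            state = {}
            for n in names:
                d = dis[n][sex]
                c0 = float(d.loc[a0, "prevalence"]) if a0 >= bundle.diseases[n].min_age else 0.0
                state[n] = [1.0 - c0, c0, 0.0, 0.0]
            l = 1.0
            haly = 0.0
            cost = 0.0
            p_traj = []
            for t in range(T_global):
                age = a0 + t
                if age > 100:
                    break
                disc = (1.0 + discount_rate) ** (-float(t))
                ps = {}
                morb = float(lt[sex].loc[age, "background_pyld"])
                ccost = 0.0
                for n in names:
                    s, c, dd, do = state[n]
                    alive = s + c
                    p = c / alive if alive > 0 else 0.0
                    ps[n] = p
                    d = dis[n][sex]
                    morb += float(d.loc[age, "disability_weight"]) * p
                    ccost += p * float(d.loc[age, "annual_cost_per_case"])
                mort = float(lt[sex].loc[age, "all_cause_mortality"])
                if arm == "intervention":
                    for n in names:
                        f = float(dis[n][sex].loc[age, "case_fatality"])
                        mort += f * (ps[n] - p_base[t][n])
                mort = min(1.0, max(0.0, mort))
                haly += disc * l * (1.0 - morb)
                cost += disc * l * ccost
                for n in names:
                    d = dis[n][sex]
                    s, c, dd, do = state[n]
                    i = float(d.loc[age, "incidence"])
                    if age < bundle.diseases[n].min_age:
                        i = 0.0
                    elif arm == "intervention" and delta != 0.0:
                        mean_b, sd_b = _bmi_at_age(pop_bmi[sex], age)
                        pif = compute_pif(mean_b, sd_b, delta,
                                          float(d.loc[age, "rr_per_bmi_unit"]),
                                          tmred=tmred, form=bmi_form)
                        i = i * (1.0 - pif)
                    r = float(d.loc[age, "remission"])
                    f = float(d.loc[age, "case_fatality"])
                    m = min(1.0, max(0.0, float(lt[sex].loc[age, "all_cause_mortality"])
                                     - f * float(d.loc[age, "prevalence"])))
                    state[n] = [s - s * i + c * r - s * m,
                                c + s * i - c * r - c * f - c * m,
                                dd + c * f,
                                do + (s + c) * m]
                l = l * (1.0 - mort)
                p_traj.append(ps)
            results[arm] = {"haly": haly, "cost": cost}
            if arm == "baseline":
                p_base = p_traj
        dh = results["intervention"]["haly"] - results["baseline"]["haly"]
        dc = results["intervention"]["cost"] - results["baseline"]["cost"]
        total_h += w * dh
        total_c += w * dc
        per_cohort.append({"age": a0, "sex": sex, "delta_haly": dh, "delta_cost": dc})
    return {"halys": total_h, "healthcare_cost": total_c,
            "per_cohort": pd.DataFrame(per_cohort)}


def _bmi_at_age(pop_sex: pd.DataFrame, age: int):
    """Interpolated mean/sd BMI at a single-year age (matches engine lookup)."""
    ages = pop_sex.index.to_numpy(float)
    mean = float(np.interp(age, ages, pop_sex["mean_bmi"].to_numpy()))
    sd = float(np.interp(age, ages, pop_sex["sd_bmi"].to_numpy()))
    return mean, sd


@pytest.fixture(scope="session")
def naive_oracle():
    return naive_population_run
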