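"""Proportional multi-state life table (PMSLT) engine.

A multiple-cohort Markov model with annual cycles. Each (starting age, sex)
cohort carries a main life table whose all-cause mortality and morbidity are
adjusted by nine parallel disease sub-models. Each disease sub-model has four
states — healthy, diseased, dead from the disease, dead from other causes —
advanced by annual difference equations using incidence, remission and case
fatality. A BMI reduction enters through the potential impact fraction (PIF),
which scales incidence downward; the resulting prevalence differences change
disease mortality and years lived with disability, and hence health-adjusted
life years (HALYs) and healthcare costs, relative to the status quo arm.

Update order within a cycle t (age a = start_age + t), identical in both
arms and mirrored by the test oracles:

1. rates at age a: i = incidence * (1 - PIF) (zero below the disease's
   min_age), r = remission, f = case fatality; other-cause mortality for the
   sub-model is m = max(0, ACM(a) - f * input_prevalence(a)) so the disease's
   own deaths are not double counted.
2. record start-of-cycle outputs: alive prevalence p = C / (S + C); morbidity
   = background pYLD + sum_d dw_d * p_d; main-table mortality = ACM (baseline
   arm) or ACM + sum_d f_d * (p_d - p_d_baseline) (intervention arm).
3. accrue discounted life years l, HALYs l * (1 - morbidity), and healthcare
   cost l * sum_d p_d * cost_d, with discount factor (1 + rate)^-t (t = 0
   undiscounted, no half-cycle correction).
4. advance disease states:
       S' = S - S i + C r - S m        C' = C + S i - C r - C f - C m
       Dd' = Dd + C f                  Do' = Do + (S + C) m
   and survivors l' = l * (1 - mortality).

Relative risk is modelled as rr_per_bmi_unit raised to the BMI units above a
theoretical-minimum-risk threshold (default 21 kg/m2); the PIF integrates it
over the baseline and mean-shifted BMI distributions on a fixed bounded BMI
grid (trapezoid rule, renormalised over the grid). The bounded support is
deliberate: an exponential risk function has no finite expectation under an
unbounded lognormal, so the distribution is truncated to the physiologically
meaningful BMI range. The PIF is exactly zero for a null shift or flat risk.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    AGE_MAX,
    AGE_MIN,
    AGES,
    ConfigurationError,
    DiseaseSpec,
    InputBundle,
    ModelOutputs,
)

DEFAULT_TMRED = 21.0
#: Bounded BMI integration grid: (low, high, points); step 0.5 kg/m2 puts the
#: default risk threshold exactly on a node.
DEFAULT_GRID = (10.0, 60.0, 101)

_N_AGE = AGE_MAX - AGE_MIN + 1

_grid_cache: dict = {}


def _bmi_grid(grid):
    if grid not in _grid_cache:
        lo, hi, n = grid
        x = np.linspace(lo, hi, int(n))
        tw = np.full(int(n), x[1] - x[0])
        tw[0] = tw[-1] = (x[1] - x[0]) / 2.0  # trapezoid end weights
        _grid_cache[grid] = (x, tw)
    return _grid_cache[grid]


def discount_stream(values, rate: float, t_start: int = 0) -> float:
    """Present value of a per-cycle stream: sum v_t (1+rate)^-(t_start+t)."""
    if rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    v = np.asarray(values, dtype=float)
    t = np.arange(v.size) + t_start
    return float(np.sum(v * (1.0 + rate) ** (-t.astype(float))))


def compute_pif_discrete(p_base, p_shift, rr) -> float:
    """PIF for a discrete exposure distribution (oracle path).

    ``p_base`` and ``p_shift`` are group probabilities (each summing to 1)
    and ``rr`` the group relative risks:
    PIF = (sum p rr - sum p' rr) / (sum p rr).
    """
    p_base = np.asarray(p_base, dtype=float)
    p_shift = np.asarray(p_shift, dtype=float)
    rr = np.asarray(rr, dtype=float)
    eb = float(p_base @ rr)
    es = float(p_shift @ rr)
    return (eb - es) / eb


def compute_pif(
    mean,
    sd,
    delta,
    rr_per_unit,
    tmred: float = DEFAULT_TMRED,
    form: str = "lognormal",
    grid=DEFAULT_GRID,
    shifted_sd=None,
):
    """Potential impact fraction for a mean shift of the BMI distribution.

    The baseline distribution has the given arithmetic ``mean``/``sd`` (of
    lognormal or normal ``form``); the shifted distribution has mean + delta
    with the same sd. RR(x) = rr_per_unit ** max(0, x - tmred), integrated
    on a fixed bounded BMI grid. Broadcasts over array inputs; returns PIF
    in (-inf, 1], exactly 0 for delta = 0 or rr_per_unit = 1.
    """
    mean, sd, delta, rr = np.broadcast_arrays(
        np.asarray(mean, float), np.asarray(sd, float),
        np.asarray(delta, float), np.asarray(rr_per_unit, float))
    if shifted_sd is not None and not np.allclose(shifted_sd, sd):
        raise ValueError("baseline and shifted distributions must share sd")
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    if np.any(rr < 0):
        raise ValueError("rr_per_unit must be >= 0")
    x, tw = _bmi_grid(grid)
    rrx = np.power(rr[..., None], np.maximum(0.0, x - tmred))

    def expectation(m):
        if form == "lognormal":
            if np.any(m <= 0):
                raise ValueError("lognormal BMI mean must be positive")
            s2 = np.log1p((sd / m) ** 2)
            mu = np.log(m) - s2 / 2.0
            z = np.log(x) - mu[..., None]
            pdf = np.exp(-0.5 * z**2 / s2[..., None]) / (x * np.sqrt(2.0 * np.pi * s2[..., None]))
        elif form == "normal":
            z = (x - m[..., None]) / sd[..., None]
            pdf = np.exp(-0.5 * z**2) / (sd[..., None] * np.sqrt(2.0 * np.pi))
        else:
            raise ConfigurationError(f"unknown BMI distribution form {form!r}")
        w = pdf * tw
        return (rrx * w).sum(axis=-1) / w.sum(axis=-1)

    e_base = expectation(mean)
    e_shift = expectation(mean + delta)
    out = (e_base - e_shift) / e_base
    return float(out) if out.ndim == 0 else out


def compute_icer(halys: float, net_cost: float):
    """ICER = net cost / incremental HALYs, with dominance labels.

    More health at lower cost is "Dominant" (no ratio reported); less health
    at higher cost is "Dominated"; zero health gain is undefined.
    """
    if halys > 0 and net_cost < 0:
        return "Dominant"
    if halys < 0 and net_cost > 0:
        return "Dominated"
    if halys == 0:
        return "undefined (no health gain)"
    return net_cost / halys


# ---------------------------------------------------------------------------
# Engine internals
# ---------------------------------------------------------------------------


@dataclass
class _SexData:
    """Per-sex rate matrices indexed by age row (age - 2) and disease column."""

    diseases: Sequence[str]
    inc: np.ndarray
    prev: np.ndarray
    cf: np.ndarray
    rem: np.ndarray
    dw: np.ndarray
    cost: np.ndarray
    rr: np.ndarray
    min_age: np.ndarray
    acm: np.ndarray
    pyld: np.ndarray
    mean_bmi: np.ndarray
    sd_bmi: np.ndarray


@dataclass
class _ArmResult:
    haly: np.ndarray          # (n_cohort,) discounted HALYs per start person
    ly: np.ndarray            # (n_cohort,) discounted life years
    cost_by_disease: np.ndarray  # (n_cohort, n_disease) discounted A$ per start person
    p: np.ndarray             # (n_cohort, T, n_disease) alive prevalence
    max_conservation_error: float
    haly_stream: np.ndarray   # (T,) discounted, weighted by cohort counts
    cost_stream: np.ndarray   # (T,)
    detail: Optional[dict] = None


def _build_sex_data(bundle: InputBundle, sex: str) -> _SexData:
    names = list(bundle.diseases)
    nd = len(names)
    mats = {k: np.zeros((_N_AGE, nd)) for k in
            ("inc", "prev", "cf", "rem", "dw", "cost", "rr")}
    min_age = np.zeros(nd, dtype=int)
    cols = {"inc": "incidence", "prev": "prevalence", "cf": "case_fatality",
            "rem": "remission", "dw": "disability_weight",
            "cost": "annual_cost_per_case", "rr": "rr_per_bmi_unit"}
    for d, name in enumerate(names):
        spec = bundle.diseases[name]
        t = spec.table
        sub = t[t["sex"] == sex].set_index("age").reindex(AGES)
        for k, col in cols.items():
            mats[k][:, d] = sub[col].to_numpy()
        min_age[d] = spec.min_age
    lt = bundle.lifetable
    ltx = lt[lt["sex"] == sex].set_index("age").reindex(AGES)
    pop = bundle.population[bundle.population["sex"] == sex]
    # anthropometry by single-year age; a collapsed population still needs
    # values at every age the cohorts pass through, so interpolate
    bmi = pop.set_index("age")["mean_bmi"]
    sdb = pop.set_index("age")["sd_bmi"]
    ages = np.asarray(AGES, float)
    if len(bmi) == 0:  # no cohorts of this sex in the population table
        mean_bmi = np.full(_N_AGE, np.nan)
        sd_bmi = np.full(_N_AGE, np.nan)
    else:
        mean_bmi = np.interp(ages, bmi.index.to_numpy(float), bmi.to_numpy())
        sd_bmi = np.interp(ages, sdb.index.to_numpy(float), sdb.to_numpy())
    return _SexData(
        diseases=names, min_age=min_age,
        acm=ltx["all_cause_mortality"].to_numpy(),
        pyld=ltx["background_pyld"].to_numpy(),
        mean_bmi=mean_bmi, sd_bmi=sd_bmi, **mats,
    )


def _run_arm(
    sd: _SexData,
    start_ages: np.ndarray,
    counts: np.ndarray,
    discount_rate: float,
    horizon: int,
    pif: Optional[np.ndarray] = None,
    base: Optional[_ArmResult] = None,
    detail: bool = False,
) -> _ArmResult:
    n_c = start_ages.size
    n_d = len(sd.diseases)
    T = horizon
    agemask0 = start_ages[:, None] >= sd.min_age[None, :]
    idx0 = np.clip(start_ages - AGE_MIN, 0, _N_AGE - 1)
    C = np.where(agemask0, sd.prev[idx0, :], 0.0)
    S = 1.0 - C
    Dd = np.zeros((n_c, n_d))
    Do = np.zeros((n_c, n_d))
    l = np.ones(n_c)
    haly = np.zeros(n_c)
    ly = np.zeros(n_c)
    cost_by_d = np.zeros((n_c, n_d))
    p_store = np.zeros((n_c, T, n_d))
    haly_stream = np.zeros(T)
    cost_stream = np.zeros(T)
    max_err = 0.0
    det = {"survivors": np.zeros((n_c, T)), "life_years": np.zeros((n_c, T)),
           "halys": np.zeros((n_c, T)), "healthcare_cost": np.zeros((n_c, T)),
           "morbidity": np.zeros((n_c, T))} if detail else None

    for t in range(T):
        age = start_ages + t
        active = age <= AGE_MAX
        if not active.any():
            break
        idx = np.clip(age - AGE_MIN, 0, _N_AGE - 1)
        inc_t = sd.inc[idx, :]
        if pif is not None:
            inc_t = inc_t * (1.0 - pif[:, t, :])
        agemask = age[:, None] >= sd.min_age[None, :]
        inc_t = np.where(agemask, inc_t, 0.0)
        rem_t = sd.rem[idx, :]
        cf_t = sd.cf[idx, :]
        m_o = np.clip(sd.acm[idx][:, None] - cf_t * sd.prev[idx, :], 0.0, 1.0)

        alive = S + C
        p = np.where(alive > 0, C / np.where(alive > 0, alive, 1.0), 0.0)
        p_store[:, t, :] = np.where(active[:, None], p, 0.0)

        morb = sd.pyld[idx] + (sd.dw[idx, :] * p).sum(axis=1)
        if np.any(morb[active] >= 1.0):
            raise ValueError(f"morbidity adjustment >= 1 at cycle {t}")
        mort = sd.acm[idx].copy()
        if base is not None:
            mort = mort + (cf_t * (p - base.p[:, t, :])).sum(axis=1)
        mort = np.clip(mort, 0.0, 1.0)

        disc = (1.0 + discount_rate) ** (-float(t))
        contrib = np.where(active, l, 0.0)
        ly += disc * contrib
        h_t = contrib * (1.0 - morb)
        haly += disc * h_t
        c_t = contrib[:, None] * p * sd.cost[idx, :]
        cost_by_d += disc * c_t
        haly_stream[t] = disc * float(counts @ h_t)
        cost_stream[t] = disc * float(counts @ c_t.sum(axis=1))
        if detail:
            det["survivors"][:, t] = contrib
            det["life_years"][:, t] = contrib
            det["halys"][:, t] = h_t
            det["healthcare_cost"][:, t] = c_t.sum(axis=1)
            det["morbidity"][:, t] = morb

        am = active[:, None]
        dS = -S * inc_t + C * rem_t - S * m_o
        dC = S * inc_t - C * rem_t - C * cf_t - C * m_o
        dDd = C * cf_t
        dDo = (S + C) * m_o
        S = np.where(am, S + dS, S)
        C = np.where(am, C + dC, C)
        Dd = np.where(am, Dd + dDd, Dd)
        Do = np.where(am, Do + dDo, Do)
        err = float(np.abs((S + C + Dd + Do) - 1.0).max())
        max_err = max(max_err, err)
        if err > 1e-6:
            raise RuntimeError(f"state occupancy conservation violated at cycle {t}: {err}")
        l = np.where(active, l * (1.0 - mort), l)

    return _ArmResult(haly=haly, ly=ly, cost_by_disease=cost_by_d, p=p_store,
                      max_conservation_error=max_err, haly_stream=haly_stream,
                      cost_stream=cost_stream, detail=det)


class PMSLTModel:
    """Multiple-cohort PMSLT for a fixed discount rate and horizon.

    The status-quo arm depends only on the epidemiological inputs, so it is
    computed once and cached; ``evaluate`` reruns only the intervention arm,
    which makes repeated probabilistic-sensitivity evaluations cheap.
    """

    def __init__(
        self,
        bundle: InputBundle,
        discount_rate: float = 0.03,
        horizon_years: Optional[int] = None,
        tmred: float = DEFAULT_TMRED,
        bmi_form: str = "lognormal",
        grid=DEFAULT_GRID,
    ) -> None:
        if discount_rate < 0:
            raise ConfigurationError("discount rate must be >= 0")
        self.bundle = bundle
        self.discount_rate = discount_rate
        lifetime = AGE_MAX - AGE_MIN + 1
        self.horizon = lifetime if horizon_years is None else min(int(horizon_years), lifetime)
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1 year")
        self.tmred = tmred
        self.bmi_form = bmi_form
        self.grid = grid
        self._sexdata = {}
        self._cohorts = {}
        for sex in ("male", "female"):
            pop = bundle.population[bundle.population["sex"] == sex].sort_values("age")
            self._cohorts[sex] = (
                pop["age"].to_numpy(dtype=int),
                pop["count"].to_numpy(dtype=float),
            )
            self._sexdata[sex] = _build_sex_data(bundle, sex)
        self._baseline: dict = {}

    def baseline(self, sex: str) -> _ArmResult:
        if sex not in self._baseline:
            ages, counts = self._cohorts[sex]
            self._baseline[sex] = _run_arm(
                self._sexdata[sex], ages, counts, self.discount_rate, self.horizon)
        return self._baseline[sex]

    def _pif_tensor(self, sex: str, delta: np.ndarray,
                    rr_scale: Optional[np.ndarray]) -> np.ndarray:
        sd = self._sexdata[sex]
        ages0, _ = self._cohorts[sex]
        n_c = ages0.size
        n_d = len(sd.diseases)
        T = self.horizon
        t_idx = np.arange(T)
        ages = ages0[:, None] + t_idx[None, :]
        valid = ages <= AGE_MAX
        idx = np.clip(ages - AGE_MIN, 0, _N_AGE - 1)
        mean = sd.mean_bmi[idx]
        sdev = sd.sd_bmi[idx]
        dmat = np.broadcast_to(delta[:, None], ages.shape)
        pif = np.zeros((n_c, T, n_d))
        for d in range(n_d):
            mask = valid & (ages >= sd.min_age[d]) & (dmat != 0.0)
            if not mask.any():
                continue
            rr = sd.rr[idx, d]
            if rr_scale is not None:
                rr = rr * rr_scale[d]
            pif[:, :, d][mask] = compute_pif(
                mean[mask], sdev[mask], dmat[mask], rr[mask],
                tmred=self.tmred, form=self.bmi_form, grid=self.grid)
        return pif

    def evaluate(
        self,
        impact: pd.DataFrame,
        rr_scale: Optional[np.ndarray] = None,
        cost_scale: Optional[np.ndarray] = None,
        detail: bool = False,
    ) -> dict:
        """Incremental HALYs and healthcare cost for a BMI impact table.

        ``impact`` must carry one row per population cohort with delta_bmi;
        ``rr_scale``/``cost_scale`` are optional per-disease multipliers
        (probabilistic draws). Returns a dict with halys, healthcare_cost,
        conservation error, and per-cycle streams.
        """
        total_haly = 0.0
        total_cost = 0.0
        max_err = 0.0
        streams = None
        for sex in ("male", "female"):
            ages, counts = self._cohorts[sex]
            base = self.baseline(sex)
            imp = impact[impact["sex"] == sex].set_index("age")["delta_bmi"].reindex(ages)
            delta = imp.to_numpy(dtype=float)
            if np.any(np.isnan(delta)):
                raise ValueError(f"impact table missing cohorts for sex={sex}")
            pif = self._pif_tensor(sex, delta, rr_scale)
            inter = _run_arm(self._sexdata[sex], ages, counts, self.discount_rate,
                             self.horizon, pif=pif, base=base, detail=detail)
            total_haly += float(counts @ (inter.haly - base.haly))
            dcost = inter.cost_by_disease - base.cost_by_disease
            if cost_scale is not None:
                dcost = dcost * cost_scale[None, :]
            total_cost += float(counts @ dcost.sum(axis=1))
            max_err = max(max_err, base.max_conservation_error,
                          inter.max_conservation_error)
            frame = pd.DataFrame({
                "cycle": np.arange(self.horizon),
                f"haly_baseline_{sex}": base.haly_stream,
                f"haly_intervention_{sex}": inter.haly_stream,
                f"cost_baseline_{sex}": base.cost_stream,
                f"cost_intervention_{sex}": inter.cost_stream,
            }).set_index("cycle")
            streams = frame if streams is None else streams.join(frame)
        return {
            "halys": total_haly,
            "healthcare_cost": total_cost,
            "conservation_error": max_err,
            "streams": streams.reset_index(),
        }


def run_disease_submodel(
    spec: DiseaseSpec,
    pif_by_age: Mapping[int, float],
    lifetable: pd.DataFrame,
    sex: str,
    start_age: Optional[int] = None,
    n_cycles: Optional[int] = None,
) -> pd.DataFrame:
    """Single-cohort four-state disease trajectory (reference scalar path).

    ``pif_by_age`` maps age to the incidence reduction fraction (missing ages
    mean zero). Returns one row per cycle with the four occupancies, alive
    prevalence, the disease's excess mortality f*p and YLD p*dw.
    """
    t = spec.table
    sub = t[t["sex"] == sex].set_index("age")
    lt = lifetable[lifetable["sex"] == sex].set_index("age")
    a0 = int(start_age if start_age is not None else sub.index.min())
    last = int(sub.index.max())
    T = (last - a0 + 1) if n_cycles is None else min(n_cycles, last - a0 + 1)
    c = float(sub.loc[a0, "prevalence"]) if a0 >= spec.min_age else 0.0
    s = 1.0 - c
    dd = 0.0
    do = 0.0
    rows = []
    for cyc in range(T):
        age = a0 + cyc
        i = float(sub.loc[age, "incidence"]) * (1.0 - float(pif_by_age.get(age, 0.0)))
        if age < spec.min_age:
            i = 0.0
        r = float(sub.loc[age, "remission"])
        f = float(sub.loc[age, "case_fatality"])
        m = max(0.0, float(lt.loc[age, "all_cause_mortality"])
                - f * float(sub.loc[age, "prevalence"]))
        alive = s + c
        p = c / alive if alive > 0 else 0.0
        rows.append({
            "cycle": cyc, "age": age, "healthy": s, "diseased": c,
            "dead_disease": dd, "dead_other": do, "prevalence": p,
            "excess_mortality": f * p,
            "yld": p * float(sub.loc[age, "disability_weight"]),
        })
        s, c, dd, do = (s - s * i + c * r - s * m,
                        c + s * i - c * r - c * f - c * m,
                        dd + c * f,
                        do + (s + c) * m)
    return pd.DataFrame(rows)


def run_cohort(
    start_age: int,
    sex: str,
    delta_bmi: float,
    bundle: InputBundle,
    discount_rate: float = 0.03,
    horizon_years: Optional[int] = None,
    tmred: float = DEFAULT_TMRED,
    bmi_form: str = "lognormal",
) -> tuple:
    """Baseline and intervention life tables for one cohort.

    Returns (baseline_frame, intervention_frame); each has one row per cycle
    with survivors, life_years, halys and healthcare_cost (undiscounted), and
    the discount factor applied by the aggregate accounting.
    """
    pop = bundle.population
    row = pop[(pop["sex"] == sex) & (pop["age"] == start_age)]
    if row.empty:
        raise ValueError(f"no population cohort at age {start_age}, sex {sex}")
    single = InputBundle(
        population=row, intake=bundle.intake, diseases=bundle.diseases,
        lifetable=bundle.lifetable, wages=bundle.wages,
        cost_config=bundle.cost_config, scale=bundle.scale)
    model = PMSLTModel(single, discount_rate=discount_rate,
                       horizon_years=horizon_years, tmred=tmred, bmi_form=bmi_form)
    # restrict horizon to this cohort's remaining lifetime
    model.horizon = min(model.horizon, AGE_MAX - start_age + 1)
    ages, counts = model._cohorts[sex]
    sdat = model._sexdata[sex]
    base = _run_arm(sdat, ages, counts, discount_rate, model.horizon, detail=True)
    pif = model._pif_tensor(sex, np.asarray([delta_bmi], float), None)
    inter = _run_arm(sdat, ages, counts, discount_rate, model.horizon,
                     pif=pif, base=base, detail=True)

    def frame(arm: _ArmResult) -> pd.DataFrame:
        T = model.horizon
        t = np.arange(T)
        return pd.DataFrame({
            "cycle": t,
            "age": start_age + t,
            "survivors": arm.detail["survivors"][0],
            "life_years": arm.detail["life_years"][0],
            "halys": arm.detail["halys"][0],
            "healthcare_cost": arm.detail["healthcare_cost"][0],
            "discount_factor": (1.0 + discount_rate) ** (-t.astype(float)),
        })

    return frame(base), frame(inter)


def run_population(
    bundle: InputBundle,
    impact: pd.DataFrame,
    intervention_cost_summary,
    discount_rate: float = 0.03,
    horizon_years: Optional[int] = None,
    tmred: float = DEFAULT_TMRED,
    bmi_form: str = "lognormal",
) -> ModelOutputs:
    """Population-level incremental outputs of intervention vs status quo."""
    model = PMSLTModel(bundle, discount_rate=discount_rate,
                       horizon_years=horizon_years, tmred=tmred, bmi_form=bmi_form)
    res = model.evaluate(impact)
    return ModelOutputs(
        halys=res["halys"],
        healthcare_cost=res["healthcare_cost"],
        intervention_cost=intervention_cost_summary.grand_total_discounted,
        government_cost=intervention_cost_summary.discounted["government"],
        industry_cost=intervention_cost_summary.discounted["industry"],
        conservation_error=res["conservation_error"],
        streams=res["streams"],
    )
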