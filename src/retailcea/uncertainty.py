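"""Probabilistic sensitivity analysis and deterministic scenario analyses.

The PSA is a Monte Carlo propagation: every uncertain input gets a
probability distribution, each draw jointly samples all of them, reruns the
whole pipeline (effect pathway -> costing -> life table model), and the
resulting pairs of incremental HALYs and net cost are summarised as means
with empirical 95% uncertainty intervals and classified on the
cost-effectiveness plane. One master seed with per-draw substreams makes
runs bit-reproducible and lets scenarios share common random numbers.

Distribution families by parameter class (declared defaults): the effect
size is truncated-normal on [0, 1]; relative risks per BMI unit get a
lognormal multiplier truncated so the risk direction (RR >= 1) is preserved,
reflecting the consistent direction of the epidemiological evidence; unit
costs get gamma multipliers; the per-product assessment time is uniform on
its stated 5-10 minute range. Parameters are sampled independently.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import costing, effect_pathway, pmslt
from .config import RunConfig
from .types import CoverageFactors, EffectEstimate, InputBundle, ModelOutputs

_FAMILIES = ("normal", "lognormal", "gamma", "uniform", "beta", "degenerate")


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: family, parameters, truncation bounds."""

    name: str
    family: str
    params: Mapping[str, float]
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator) -> float:
        p = self.params
        for _ in range(1000):
            if self.family == "degenerate":
                x = float(p["value"])
            elif self.family == "normal":
                x = float(rng.normal(p["mean"], p["sd"]))
            elif self.family == "lognormal":
                x = float(p["median"] * math.exp(rng.normal(0.0, p["sigma"])))
            elif self.family == "gamma":
                cv = float(p["cv"])
                if cv == 0:
                    x = float(p["mean"])
                else:
                    shape = 1.0 / cv**2
                    x = float(rng.gamma(shape, p["mean"] * cv**2))
            elif self.family == "uniform":
                x = float(rng.uniform(p["lo"], p["hi"]))
            else:  # beta
                x = float(rng.beta(p["a"], p["b"]))
            if self.lo <= x <= self.hi:
                return x
            if self.family == "degenerate":
                break
        raise RuntimeError(f"distribution for {self.name!r} cannot produce an in-domain draw")


@dataclass
class PSAResult:
    """Per-draw results plus summaries and CE-plane quadrant counts."""

    draws: pd.DataFrame
    summary: pd.DataFrame
    quadrant_counts: Dict[str, int]
    seed: int

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def build_parameter_set(config: RunConfig, bundle: InputBundle,
                        degenerate: bool = False) -> Dict[str, ParameterDistribution]:
    """The default PSA parameter catalogue for a run.

    With ``degenerate=True`` every distribution collapses to its point value
    (the PSA then reproduces the deterministic run draw for draw).
    """
    effect_point = (config.effect_point if config.effect_point is not None
                    else effect_pathway.combine_effect_sizes(config.effect_studies).point)
    lo_min, hi_min = (float(x) for x in bundle.cost_config["assessment_minutes"])
    mid_min = (lo_min + hi_min) / 2.0
    params: Dict[str, ParameterDistribution] = {}

    def add(name, family, p, lo=-math.inf, hi=math.inf, point=None):
        if degenerate:
            params[name] = ParameterDistribution(name, "degenerate", {"value": point})
        else:
            params[name] = ParameterDistribution(name, family, p, lo, hi)

    add("effect", "normal", {"mean": effect_point, "sd": config.effect_sd},
        lo=0.0, hi=1.0, point=effect_point)
    add("assessment_minutes", "uniform", {"lo": lo_min, "hi": hi_min}, point=mid_min)
    for name in bundle.diseases:
        rr_point = float(bundle.diseases[name].table["rr_per_bmi_unit"].iloc[0])
        lo = 1.0 / rr_point if rr_point > 1.0 else 1.0
        add(f"rr:{name}", "lognormal", {"median": 1.0, "sigma": config.rr_sigma},
            lo=lo, point=1.0)
        add(f"hc_cost:{name}", "gamma", {"mean": 1.0, "cv": config.healthcare_cost_cv},
            lo=0.0, point=1.0)
    for label, cv in config.cost_cv.items():
        add(f"cost:{label}", "gamma", {"mean": 1.0, "cv": float(cv)}, lo=0.0, point=1.0)
    return params


def _effect_estimate(config: RunConfig) -> EffectEstimate:
    if config.effect_point is not None:
        return EffectEstimate(point=config.effect_point)
    return effect_pathway.combine_effect_sizes(config.effect_studies)


def _cost_summary(bundle: InputBundle, config: RunConfig, cycles: int,
                  minutes: Optional[float] = None,
                  fixed_scale: Optional[Mapping[str, float]] = None):
    cost_horizon = cycles - 1  # years 0..cycles-1 align with model cycles
    items = costing.assemble_costs(
        bundle.wages, bundle.cost_config, cost_horizon,
        assessment_minutes=minutes,
        layout_days_multiplier=config.layout_days_multiplier,
        fixed_scale=fixed_scale,
    )
    return costing.summarise_costs(items, config.discount_rate, cost_horizon)


def deterministic_run(bundle: InputBundle, config: RunConfig,
                      model: Optional[pmslt.PMSLTModel] = None) -> dict:
    """One full pipeline evaluation at point values.

    Returns impact table and its population means, the cost summary, the
    ModelOutputs and the ICER value or dominance label.
    """
    effect = _effect_estimate(config)
    factors = CoverageFactors(config.market_share, config.supermarket_share)
    impact = effect_pathway.body_impact(
        bundle.population, bundle.intake, factors, effect,
        categories=config.categories,
        adult_kj_per_kg=config.adult_kj_per_kg,
        child_kj_per_kg=config.child_kj_per_kg,
    )
    if model is None:
        model = pmslt.PMSLTModel(
            bundle, discount_rate=config.discount_rate,
            horizon_years=config.horizon_years,
            tmred=config.tmred, bmi_form=config.bmi_form)
    res = model.evaluate(impact)
    summary = _cost_summary(bundle, config, model.horizon)
    outputs = ModelOutputs(
        halys=res["halys"], healthcare_cost=res["healthcare_cost"],
        intervention_cost=summary.grand_total_discounted,
        government_cost=summary.discounted["government"],
        industry_cost=summary.discounted["industry"],
        conservation_error=res["conservation_error"],
        streams=res["streams"],
    )
    return {
        "impact": impact,
        "impact_means": effect_pathway.population_means(impact),
        "cost_summary": summary,
        "outputs": outputs,
        "icer": pmslt.compute_icer(outputs.halys, outputs.net_cost),
        "model": model,
    }


def _fixed_scale_from_draws(draws: Mapping[str, float],
                            monitoring_years: int) -> Dict[str, float]:
    scale = {}
    for key, value in draws.items():
        if not key.startswith("cost:"):
            continue
        label = key.split(":", 1)[1]
        if label == "monitoring":
            for y in range(1, monitoring_years + 1):
                scale[f"monitoring_year_{y}"] = value
        else:
            scale[label] = value
    return scale


def run_psa(bundle: InputBundle, config: RunConfig, n_draws: Optional[int] = None,
            seed: Optional[int] = None, degenerate: bool = False) -> PSAResult:
    """Monte Carlo PSA: jointly sampled parameters, full pipeline per draw."""
    n = int(n_draws if n_draws is not None else config.psa_draws)
    if n < 1:
        raise ValueError("n_draws must be >= 1")
    seed = int(seed if seed is not None else config.seed)
    param_set = build_parameter_set(config, bundle, degenerate=degenerate)
    names = sorted(param_set)
    disease_names = list(bundle.diseases)
    mon_years = int(bundle.cost_config["monitoring"]["years"])
    factors = CoverageFactors(config.market_share, config.supermarket_share)
    model = pmslt.PMSLTModel(
        bundle, discount_rate=config.discount_rate,
        horizon_years=config.horizon_years,
        tmred=config.tmred, bmi_form=config.bmi_form)
    for sex in ("male", "female"):
        model.baseline(sex)  # cache the status-quo arm once

    substreams = np.random.SeedSequence(seed).spawn(n)
    records = []
    for k in range(n):
        rng = np.random.default_rng(substreams[k])
        draw = {name: param_set[name].sample(rng) for name in names}
        effect = EffectEstimate(point=min(1.0, max(0.0, draw["effect"])))
        impact = effect_pathway.body_impact(
            bundle.population, bundle.intake, factors, effect,
            categories=config.categories,
            adult_kj_per_kg=config.adult_kj_per_kg,
            child_kj_per_kg=config.child_kj_per_kg,
        )
        rr_scale = np.array([draw[f"rr:{d}"] for d in disease_names])
        cost_scale = np.array([draw[f"hc_cost:{d}"] for d in disease_names])
        res = model.evaluate(impact, rr_scale=rr_scale, cost_scale=cost_scale)
        summary = _cost_summary(
            bundle, config, model.horizon,
            minutes=draw["assessment_minutes"],
            fixed_scale=_fixed_scale_from_draws(draw, mon_years),
        )
        interv = summary.grand_total_discounted
        records.append({
            "draw": k,
            "effect": effect.point,
            "halys": res["halys"],
            "healthcare_cost": res["healthcare_cost"],
            "intervention_cost": interv,
            "government_cost": summary.discounted["government"],
            "industry_cost": summary.discounted["industry"],
            "net_cost": interv + res["healthcare_cost"],
        })
    draws = pd.DataFrame(records)
    quantities = ["halys", "healthcare_cost", "intervention_cost",
                  "government_cost", "industry_cost", "net_cost"]
    summary_rows = [
        {"quantity": q, "mean": float(draws[q].mean()),
         "ui_lower": float(np.percentile(draws[q], 2.5)),
         "ui_upper": float(np.percentile(draws[q], 97.5))}
        for q in quantities
    ]
    plane = ce_plane(draws)
    counts = plane["quadrant"].value_counts().to_dict()
    return PSAResult(draws=draws, summary=pd.DataFrame(summary_rows),
                     quadrant_counts={k: int(v) for k, v in counts.items()},
                     seed=seed)


def ce_plane(draws: pd.DataFrame) -> pd.DataFrame:
    """Cost-effectiveness-plane quadrant per draw.

    Southeast (gain health, save money) is ``halys > 0 and net_cost < 0``;
    exact zeros on both axes map to "origin" and a single zero to "axis".
    """
    h = draws["halys"].to_numpy()
    c = draws["net_cost"].to_numpy()
    quad = np.select(
        [(h == 0) & (c == 0), (h == 0) | (c == 0),
         (h > 0) & (c < 0), (h > 0) & (c > 0),
         (h < 0) & (c > 0), (h < 0) & (c < 0)],
        ["origin", "axis", "southeast", "northeast", "northwest", "southwest"],
        default="axis",
    )
    out = draws[["draw", "halys", "net_cost"]].copy()
    out["quadrant"] = quad
    return out


#: Deterministic scenario analyses: config overrides per scenario id.
SCENARIOS: Dict[str, dict] = {
    "SA1": {"discount_rate": 0.07},
    "SA2": {"discount_rate": 0.10},
    "SA3": {"layout_days_multiplier": 3.0},
    "SA4": {"categories": ["chocolate_confectionery"]},
    "SA5": {"horizon": 10},
}


def run_scenarios(bundle: InputBundle, config: RunConfig,
                  ids: Sequence[str] = ("SA1", "SA2", "SA3", "SA4", "SA5"),
                  include_primary: bool = True) -> pd.DataFrame:
    """One deterministic pipeline run per scenario (plus the primary run)."""
    rows = []
    labels = (["primary"] if include_primary else []) + list(ids)
    for sid in labels:
        if sid == "primary":
            cfg = config
        else:
            if sid not in SCENARIOS:
                raise KeyError(f"unknown scenario id {sid!r}")
            cfg = config.with_overrides(**SCENARIOS[sid])
        res = deterministic_run(bundle, cfg)
        means = res["impact_means"].set_index("sex")
        out = res["outputs"]
        rows.append({
            "scenario": sid,
            "mean_delta_bmi_male": float(means.loc["male", "mean_delta_bmi"]),
            "mean_delta_bmi_female": float(means.loc["female", "mean_delta_bmi"]),
            "intervention_cost": out.intervention_cost,
            "healthcare_cost": out.healthcare_cost,
            "net_cost": out.net_cost,
            "halys": out.halys,
            "icer": res["icer"],
        })
    return pd.DataFrame(rows)
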