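"""Publication-style output tables, run logging, and the pipeline driver.

Currency is reported in millions of A$ with two decimals; negative values
denote savings. Every table is written both as CSV and as a plain-text
rendering, and a run log captures the seed, the configuration hash and every
parameter value used, so each reported number traces to a logged input.
"""
from __future__ import annotations

import datetime
import logging
import os
from typing import Optional

import pandas as pd
import yaml

from . import pmslt, synthetic_data, uncertainty
from .config import RunConfig
from .types import InputBundle, ModelOutputs

log = logging.getLogger("retailcea")


def millions(x: float) -> float:
    return round(x / 1e6, 2)


def effectiveness_table(impact_means: pd.DataFrame) -> pd.DataFrame:
    """Mean per-person changes in daily energy, weight and BMI by sex."""
    m = impact_means.set_index("sex")
    return pd.DataFrame(
        {
            "males": [m.loc["male", "mean_delta_kj"], m.loc["male", "mean_delta_weight"],
                      m.loc["male", "mean_delta_bmi"]],
            "females": [m.loc["female", "mean_delta_kj"], m.loc["female", "mean_delta_weight"],
                        m.loc["female", "mean_delta_bmi"]],
        },
        index=["mean_change_kj_per_day", "mean_change_weight_kg", "mean_change_bmi_kg_m2"],
    ).round(4)


def costs_table(cost_summary) -> pd.DataFrame:
    """Per-item and per-sector discounted costs in A$ millions."""
    items = cost_summary.items.copy()
    items["discounted_m"] = items["discounted"].map(millions)
    rows = items[["label", "sector", "year", "duration", "discounted_m"]]
    sector = pd.DataFrame(
        [
            {"label": f"total_{s}", "sector": s, "year": "", "duration": "",
             "discounted_m": millions(cost_summary.discounted[s])}
            for s in cost_summary.discounted
        ]
        + [{"label": "grand_total", "sector": "all", "year": "", "duration": "",
            "discounted_m": millions(cost_summary.grand_total_discounted)}]
    )
    return pd.concat([rows, sector], ignore_index=True)


def primary_table(outputs: ModelOutputs, icer) -> pd.DataFrame:
    """Headline cost-effectiveness results (A$ millions; HALYs in millions)."""
    return pd.DataFrame(
        [
            {"result": "total_intervention_cost_m", "value": millions(outputs.intervention_cost)},
            {"result": "total_healthcare_cost_m", "value": millions(outputs.healthcare_cost)},
            {"result": "total_net_cost_m", "value": millions(outputs.net_cost)},
            {"result": "total_halys_m", "value": round(outputs.halys / 1e6, 4)},
            {"result": "icer", "value": icer if isinstance(icer, str) else round(icer, 2)},
        ]
    )


def _write_table(df: pd.DataFrame, out_dir: str, name: str, index: bool = False) -> None:
    df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=index)
    with open(os.path.join(out_dir, f"{name}.txt"), "w", encoding="utf-8") as fh:
        fh.write(df.to_string(index=index) + "\n")


def write_run_log(config: RunConfig, out_dir: str, extra: Optional[dict] = None) -> str:
    payload = {
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
    }
    if extra:
        payload["run"] = extra
    path = os.path.join(out_dir, "run_log.yaml")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def get_inputs(config: RunConfig) -> InputBundle:
    if config.data_dir:
        return synthetic_data.load_inputs(config.data_dir)
    return synthetic_data.generate_all(config.seed, scale=config.scale)


def run_pipeline(config: RunConfig, psa_draws: Optional[int] = None,
                 scenarios: bool = True) -> dict:
    """End-to-end run: inputs -> effect pathway -> costing -> life table ->
    scenarios/PSA; writes every output table under ``config.output_dir``."""
    out_dir = config.output_dir
    os.makedirs(out_dir, exist_ok=True)
    bundle = get_inputs(config)
    res = uncertainty.deterministic_run(bundle, config)
    outputs: ModelOutputs = res["outputs"]

    res["impact"].to_csv(os.path.join(out_dir, "body_impact.csv"), index=False)
    _write_table(effectiveness_table(res["impact_means"]), out_dir, "table_effectiveness", index=True)
    _write_table(costs_table(res["cost_summary"]), out_dir, "table_costs")
    res["cost_summary"].items.to_csv(os.path.join(out_dir, "costs_by_item.csv"), index=False)
    res["cost_summary"].streams.to_csv(os.path.join(out_dir, "costs_summary.csv"))
    _write_table(primary_table(outputs, res["icer"]), out_dir, "results_primary")
    outputs.streams.to_csv(os.path.join(out_dir, "per_cycle_streams.csv"), index=False)

    scenario_df = None
    if scenarios:
        scenario_df = uncertainty.run_scenarios(bundle, config)
        _write_table(scenario_df.round(4), out_dir, "scenarios")

    psa_result = None
    n = psa_draws if psa_draws is not None else 0
    if n:
        psa_result = uncertainty.run_psa(bundle, config, n_draws=n, seed=config.seed)
        psa_result.draws.to_csv(os.path.join(out_dir, "psa_draws.csv"), index=False)
        psa_result.summary.to_csv(os.path.join(out_dir, "psa_summary.csv"), index=False)
        uncertainty.ce_plane(psa_result.draws).to_csv(
            os.path.join(out_dir, "ce_plane.csv"), index=False)

    write_run_log(config, out_dir, extra={
        "horizon_cycles": res["model"].horizon,
        "icer": res["icer"] if isinstance(res["icer"], str) else float(res["icer"]),
        "halys": float(outputs.halys),
        "net_cost": float(outputs.net_cost),
        "conservation_error": float(outputs.conservation_error),
        "psa_draws": int(n),
    })
    return {"bundle": bundle, "deterministic": res, "scenarios": scenario_df,
            "psa": psa_result}
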