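"""Bottom-up policy costing: transition, ongoing, monitoring and penalties.

Costs fall to two sectors. Industry bears transition costs (head-office
regulation work, per-store familiarisation, product assessment against the
restriction criteria, store-layout changes), ongoing assessment of new
products, and non-compliance penalties. Government bears legislation, a
media campaign, complaints handling, and compliance monitoring in the first
three years. All amounts are A$ 2024; a CPI helper adjusts older figures.

Conventions: a working day is 7.6 hours; transition costs fall in year 0 and
are undiscounted under the default timing convention; ongoing costs start in
year 1; fractional store counts are retained (expected-value costing).
"""
from __future__ import annotations

from typing import Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import ConfigurationError, CostItem, CostSummary, SECTORS

DAY_HOURS = 7.6


def loaded_wage(occupation: str, wages: pd.DataFrame, prorate_leave_weeks: float = 4.0) -> float:
    """Hourly wage including on-costs and leave loading.

    base * (1 + on_cost) * (1 + leave_loading * prorate_leave_weeks / 52).
    Leave loading applies only to annual-leave weeks, so it is prorated over
    4 of 52 weeks by default; pass ``prorate_leave_weeks=52`` to load every
    hour instead.
    """
    row = wages[wages["occupation"] == occupation]
    if row.empty:
        raise KeyError(f"unknown occupation {occupation!r}")
    base = float(row["base_hourly_wage"].iloc[0])
    on_cost = float(row["on_cost_rate"].iloc[0])
    loading = float(row["leave_loading_rate"].iloc[0])
    return base * (1.0 + on_cost) * (1.0 + loading * prorate_leave_weeks / 52.0)


def _assessment_hours_per_product(cfg: Mapping, minutes: float | None) -> float:
    if minutes is None:
        lo, hi = cfg["assessment_minutes"]
        minutes = (float(lo) + float(hi)) / 2.0
    if minutes < 0:
        raise ConfigurationError("assessment minutes must be non-negative")
    return minutes / 60.0


def transition_costs(
    wages: pd.DataFrame,
    cfg: Mapping,
    assessment_minutes: float | None = None,
    layout_days_multiplier: float = 1.0,
) -> List[CostItem]:
    """One-off industry transition items, all in year 0.

    Head-office regulation work (12 h of a general manager per chain),
    per-store familiarisation (3 h retail manager + 2 x 3 h stock clerks),
    product assessment at head office (5-10 min per product on the food share
    of the range), and store-layout changes (one day each for a retail
    manager and a stock clerk plus 4 sales assistants for 1.5 days;
    ``layout_days_multiplier`` scales the day counts for scenario use).
    """
    gm = loaded_wage("general_manager", wages)
    rm = loaded_wage("retail_manager", wages)
    clerk = loaded_wage("stock_control_clerk", wages)
    assistant = loaded_wage("sales_assistant", wages)

    chains = int(cfg["chains"])
    stores = int(cfg["stores"])
    fam = cfg["familiarisation"]
    lay = cfg["layout"]
    day = float(lay.get("day_hours", DAY_HOURS))

    items = [
        CostItem("head_office_regulation", "industry",
                 quantity=chains * float(cfg["head_office_hours"]), unit_cost=gm, year=0),
        CostItem("store_familiarisation_manager", "industry",
                 quantity=stores * float(fam["manager_hours"]), unit_cost=rm, year=0),
        CostItem("store_familiarisation_clerks", "industry",
                 quantity=stores * int(fam["clerks"]) * float(fam["clerk_hours"]), unit_cost=clerk, year=0),
        CostItem("product_assessment", "industry",
                 quantity=chains * float(cfg["products_per_chain"]) * float(cfg["food_share"])
                 * _assessment_hours_per_product(cfg, assessment_minutes),
                 unit_cost=gm, year=0),
        CostItem("layout_manager", "industry",
                 quantity=stores * float(lay["manager_days"]) * layout_days_multiplier * day,
                 unit_cost=rm, year=0),
        CostItem("layout_clerk", "industry",
                 quantity=stores * float(lay["clerk_days"]) * layout_days_multiplier * day,
                 unit_cost=clerk, year=0),
        CostItem("layout_assistants", "industry",
                 quantity=stores * int(lay["assistants"]) * float(lay["assistant_days"])
                 * layout_days_multiplier * day,
                 unit_cost=assistant, year=0),
    ]
    return items


def layout_hours_per_store(cfg: Mapping, layout_days_multiplier: float = 1.0) -> float:
    """Total labour hours per store for the layout change."""
    lay = cfg["layout"]
    day = float(lay.get("day_hours", DAY_HOURS))
    days = (float(lay["manager_days"]) + float(lay["clerk_days"])
            + int(lay["assistants"]) * float(lay["assistant_days"]))
    return days * layout_days_multiplier * day


def ongoing_product_assessment(
    wages: pd.DataFrame,
    cfg: Mapping,
    horizon_years: int,
    assessment_minutes: float | None = None,
) -> List[CostItem]:
    """Annual head-office assessment of new products, years 1..horizon."""
    n_new = float(cfg["new_products_per_chain_per_year"])
    if n_new < 0:
        raise ConfigurationError("new products per chain per year must be >= 0")
    if horizon_years < 1:
        return []
    gm = loaded_wage("general_manager", wages)
    annual = int(cfg["chains"]) * n_new * float(cfg["food_share"]) \
        * _assessment_hours_per_product(cfg, assessment_minutes)
    return [CostItem("ongoing_product_assessment", "industry",
                     quantity=annual, unit_cost=gm, year=1, duration=horizon_years)]


def monitoring_and_penalties(cfg: Mapping) -> Tuple[List[CostItem], List[CostItem]]:
    """Government monitoring (years 1-3 only) and industry penalties.

    A fixed fraction of stores is checked each monitoring year; of those, the
    year-specific non-compliant share pays the penalty. Store counts stay
    fractional (expected values). Both streams are zero after the monitoring
    window closes.
    """
    mon = cfg["monitoring"]
    years = int(mon["years"])
    noncomp = [float(x) for x in mon["noncompliance"]]
    if len(noncomp) != years:
        raise ConfigurationError(
            f"non-compliance list has {len(noncomp)} entries for {years} monitoring years")
    stores = float(cfg["stores"])
    checked = stores * float(mon["check_fraction"])
    gov = [
        CostItem(f"monitoring_year_{y}", "government",
                 quantity=checked, unit_cost=float(mon["unit_cost"]), year=y)
        for y in range(1, years + 1)
    ]
    penalties = [
        CostItem(f"penalties_year_{y}", "industry",
                 quantity=checked * noncomp[y - 1], unit_cost=float(mon["penalty"]), year=y)
        for y in range(1, years + 1)
    ]
    return gov, penalties


def fixed_government_items(cfg: Mapping, horizon_years: int) -> List[CostItem]:
    """Legislation and media (one-off, year 0); complaints handling (ongoing)."""
    fixed = cfg.get("fixed")
    if fixed is None:
        raise ConfigurationError("cost config missing 'fixed' section")
    for key in ("legislation", "media", "complaints_annual"):
        if key not in fixed:
            raise ConfigurationError(f"cost config missing fixed.{key}")
    items = [
        CostItem("legislation", "government", quantity=1.0, unit_cost=float(fixed["legislation"]), year=0),
        CostItem("media_campaign", "government", quantity=1.0, unit_cost=float(fixed["media"]), year=0),
    ]
    if horizon_years >= 1:
        items.append(CostItem("complaints_handling", "government", quantity=1.0,
                              unit_cost=float(fixed["complaints_annual"]), year=1,
                              duration=horizon_years))
    return items


def adjust_to_base_year(amount: float, from_year: int, cpi_series: Mapping[int, float],
                        base_year: int = 2024) -> float:
    """Inflate/deflate an amount with the consumer price index."""
    for y in (from_year, base_year):
        if y not in cpi_series:
            raise KeyError(f"CPI series missing year {y}")
    return amount * cpi_series[base_year] / cpi_series[from_year]


def assemble_costs(
    wages: pd.DataFrame,
    cfg: Mapping,
    horizon_years: int,
    assessment_minutes: float | None = None,
    layout_days_multiplier: float = 1.0,
    fixed_scale: Mapping[str, float] | None = None,
) -> List[CostItem]:
    """All policy cost items for one run.

    ``fixed_scale`` optionally scales named fixed items (used by the PSA to
    apply sampled multipliers, e.g. {"media_campaign": 1.1}).
    """
    items = transition_costs(wages, cfg, assessment_minutes, layout_days_multiplier)
    items += ongoing_product_assessment(wages, cfg, horizon_years, assessment_minutes)
    gov, pen = monitoring_and_penalties(cfg)
    items += gov + pen + fixed_government_items(cfg, horizon_years)
    if fixed_scale:
        items = [
            CostItem(it.label, it.sector, it.quantity,
                     it.unit_cost * float(fixed_scale.get(it.label, 1.0)),
                     it.year, it.duration)
            for it in items
        ]
    return items


def summarise_costs(items: Sequence[CostItem], discount_rate: float,
                    horizon_years: int) -> CostSummary:
    """Per-sector totals and per-year streams, discounted at (1+r)^-t, t0=0.

    Item streams are truncated at the horizon; the grand total is the sum of
    sector totals by construction.
    """
    if discount_rate < 0:
        raise ConfigurationError("discount rate must be >= 0")
    years = np.arange(0, horizon_years + 1)
    streams = pd.DataFrame(0.0, index=years, columns=list(SECTORS))
    rows = []
    for it in items:
        span = [y for y in range(it.year, it.year + it.duration) if y <= horizon_years]
        for y in span:
            streams.loc[y, it.sector] += it.annual_amount
        disc = sum(it.annual_amount / (1.0 + discount_rate) ** y for y in span)
        rows.append(
            {"label": it.label, "sector": it.sector, "year": it.year,
             "duration": it.duration, "annual_amount": it.annual_amount,
             "undiscounted": it.annual_amount * len(span), "discounted": disc}
        )
    item_df = pd.DataFrame(rows)
    disc_factors = (1.0 + discount_rate) ** (-years.astype(float))
    discounted = {s: float(streams[s].to_numpy() @ disc_factors) for s in SECTORS}
    undiscounted = {s: float(streams[s].sum()) for s in SECTORS}
    return CostSummary(discounted=discounted, undiscounted=undiscounted,
                       streams=streams, discount_rate=discount_rate, items=item_df)
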