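"""Shared value types and domain constants.

The modelled population covers single-year ages 2-100 for both sexes. The
intervention restricts in-store placement of four discretionary (HFSS) food
and drink categories; downstream health impacts run through nine
obesity-related diseases in a proportional multi-state life table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

SEXES = ("male", "female")
AGE_MIN = 2
AGE_MAX = 100
AGES = tuple(range(AGE_MIN, AGE_MAX + 1))

#: Restricted discretionary product categories.
RESTRICTED_CATEGORIES = (
    "chocolate_confectionery",
    "puddings_biscuits",
    "savoury_snacks",
    "sugary_beverages",
)

#: The nine obesity-related diseases in the default catalogue.
DISEASES = (
    "ischaemic_heart_disease",
    "hypertensive_heart_disease",
    "ischaemic_stroke",
    "diabetes",
    "colorectal_cancer",
    "kidney_cancer",
    "breast_cancer",
    "endometrial_cancer",
    "osteoarthritis",
)

#: Female-only diseases (incidence held at zero for males).
FEMALE_ONLY_DISEASES = ("breast_cancer", "endometrial_cancer")

OCCUPATIONS = (
    "general_manager",
    "retail_manager",
    "stock_control_clerk",
    "sales_assistant",
    "government_officer",
)

SECTORS = ("government", "industry")


class ValidationError(ValueError):
    """An input table violates a structural or range invariant."""


class ConfigurationError(ValueError):
    """A run configuration value is missing or out of domain."""


@dataclass(frozen=True)
class EffectEstimate:
    """Proportional reduction in purchases of restricted products.

    ``point`` is a fraction in [0, 1]; ``distribution`` optionally carries the
    uncertainty specification used by the probabilistic sensitivity analysis.
    """

    point: float
    distribution: Optional[object] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.point <= 1.0:
            raise ValueError(f"effect point {self.point} outside [0, 1]")


@dataclass(frozen=True)
class CoverageFactors:
    """Market coverage applied to category intake.

    ``market_share`` is the combined market share of the supermarket chains
    the policy binds; ``supermarket_purchase_share`` is the share of category
    purchases made in supermarkets (evidence exists for chocolate; applied
    uniformly to all restricted categories by default).
    """

    market_share: float = 0.824
    supermarket_purchase_share: float = 0.76

    def __post_init__(self) -> None:
        for name in ("market_share", "supermarket_purchase_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class DiseaseSpec:
    """One obesity-related disease.

    ``table`` is indexed by (age, sex) with columns: incidence, prevalence,
    case_fatality, remission (all per person-year), disability_weight,
    annual_cost_per_case (A$ 2024 per prevalent case), rr_per_bmi_unit
    (relative risk per BMI unit above the risk threshold). ``min_age`` is the
    earliest age at which the disease accrues.
    """

    name: str
    table: pd.DataFrame
    min_age: int = 20


@dataclass
class CostItem:
    """One policy cost line: ``quantity * unit_cost`` per year of duration.

    ``year`` is the offset from policy start (transition costs at year 0,
    ongoing costs from year 1); ``duration`` is the number of consecutive
    years the annual amount recurs (1 for one-off items).
    """

    label: str
    sector: str
    quantity: float
    unit_cost: float
    year: int = 0
    duration: int = 1
    distribution: Optional[object] = None

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValueError(f"unknown sector {self.sector!r}")
        if self.quantity < 0 or self.unit_cost < 0:
            raise ValueError(f"negative quantity/unit cost on {self.label!r}")
        if self.duration < 1:
            raise ValueError(f"duration must be >= 1 on {self.label!r}")

    @property
    def annual_amount(self) -> float:
        return self.quantity * self.unit_cost

    @property
    def total_undiscounted(self) -> float:
        return self.annual_amount * self.duration


@dataclass
class CostSummary:
    """Per-sector cost totals with per-year streams.

    ``streams`` is a DataFrame indexed by year with one column per sector
    (undiscounted A$); totals are A$ at the discount rate used to build it.
    """

    discounted: Mapping[str, float]
    undiscounted: Mapping[str, float]
    streams: pd.DataFrame
    discount_rate: float
    items: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def grand_total_discounted(self) -> float:
        return float(sum(self.discounted.values()))

    @property
    def grand_total_undiscounted(self) -> float:
        return float(sum(self.undiscounted.values()))


@dataclass
class ModelOutputs:
    """Incremental results of intervention vs status quo.

    Costs are signed A$: negative healthcare cost is a saving. The net cost
    is the intervention cost plus the incremental healthcare cost.
    """

    halys: float
    healthcare_cost: float
    intervention_cost: float
    government_cost: float = 0.0
    industry_cost: float = 0.0
    conservation_error: float = 0.0
    streams: Optional[pd.DataFrame] = None

    @property
    def net_cost(self) -> float:
        return self.intervention_cost + self.healthcare_cost


@dataclass
class InputBundle:
    """All model inputs for one run.

    population: (age, sex) -> count, mean_bmi, sd_bmi, mean_height
    intake: (age, sex, category) -> kj_per_day
    diseases: name -> DiseaseSpec
    lifetable: (age, sex) -> all_cause_mortality, background_pyld
    wages: occupation -> base_hourly_wage, on_cost_rate, leave_loading_rate
    cost_config: nested dict mirroring cost_inputs.yaml
    """

    population: pd.DataFrame
    intake: pd.DataFrame
    diseases: dict
    lifetable: pd.DataFrame
    wages: pd.DataFrame
    cost_config: dict
    scale: str = "full"
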