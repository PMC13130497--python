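"""Run configuration: one YAML file drives the whole pipeline."""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import List, Mapping, Optional, Union

import yaml

from .types import AGE_MAX, AGE_MIN, RESTRICTED_CATEGORIES, ConfigurationError

LIFETIME = "lifetime"


@dataclass
class RunConfig:
    """Settings for one analysis run.

    ``horizon`` is "lifetime" (each cohort runs to age 100) or an integer
    number of years; costs and benefits are discounted at ``discount_rate``
    and expressed in base-year A$.
    """

    seed: int = 1
    scale: str = "full"
    data_dir: Optional[str] = None  # load inputs from here; None = generate
    output_dir: str = "outputs"
    base_year: int = 2024
    discount_rate: float = 0.03
    horizon: Union[str, int] = LIFETIME
    # effect pathway
    effect_studies: List[float] = field(default_factory=lambda: [0.155, 0.31 - 0.12])
    effect_point: Optional[float] = None  # overrides the study combination
    market_share: float = 0.824
    supermarket_share: float = 0.76
    categories: List[str] = field(default_factory=lambda: list(RESTRICTED_CATEGORIES))
    adult_kj_per_kg: float = 94.0
    child_kj_per_kg: float = 100.0
    # engine
    tmred: float = 21.0
    bmi_form: str = "lognormal"
    # costing scenario knob
    layout_days_multiplier: float = 1.0
    # probabilistic sensitivity analysis
    psa_draws: int = 2000
    effect_sd: float = 0.0215
    rr_sigma: float = 0.03
    healthcare_cost_cv: float = 0.15
    cost_cv: Mapping[str, float] = field(
        default_factory=lambda: {
            "media_campaign": 0.07,
            "complaints_handling": 0.45,
            "monitoring": 0.30,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ConfigurationError(f"discount_rate {self.discount_rate} outside [0, 1]")
        for name in ("market_share", "supermarket_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.horizon != LIFETIME:
            if int(self.horizon) < 1:
                raise ConfigurationError("horizon must be >= 1 year")
        unknown = set(self.categories) - set(RESTRICTED_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown categories {sorted(unknown)}")
        if self.scale not in ("small", "full"):
            raise ConfigurationError(f"unknown scale {self.scale!r}")

    @property
    def horizon_years(self) -> Optional[int]:
        """None for lifetime, else integer years."""
        return None if self.horizon == LIFETIME else int(self.horizon)

    @property
    def model_cycles(self) -> int:
        lifetime = AGE_MAX - AGE_MIN + 1
        return lifetime if self.horizon_years is None else min(self.horizon_years, lifetime)

    def with_overrides(self, **overrides) -> "RunConfig":
        """A copy with the given fields replaced (scenario machinery)."""
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cost_cv"] = dict(d["cost_cv"])
        return d

    def config_hash(self) -> str:
        dump = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(dump.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
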