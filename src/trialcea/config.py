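"""Analysis configuration: horizon, criteria, costing parameters, seeds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .costing import CapitalCostSpec
from .effectiveness import DEFAULT_CRITERIA, POPULATIONS, ResponderCriterion
from .trial_data import TrialDataError


@dataclass
class AnalysisConfig:
    """Tunable parameters of the economic evaluation.

    Defaults mirror the base case of the evaluated trial: a 6-month horizon,
    the four responder criteria, +/-20% univariate sensitivity, per-outcome
    complete-case populations, and 2018-euro costing constants (capital cost
    65.06 per patient via override, two 25.55-euro psychologist sessions,
    and a 24.53 euros/day minimum-wage valuation of sick leave).
    """

    horizon_years: float = 0.5
    criteria: Sequence[ResponderCriterion] = field(default_factory=lambda: list(DEFAULT_CRITERIA))
    perturbation: float = 0.20
    population: str = "complete_case"
    bootstrap_B: int = 1000
    seed: Optional[int] = None
    currency_year: str = "EUR 2018"
    utility_mapping: str = "passthrough"
    capital: CapitalCostSpec = field(
        default_factory=lambda: CapitalCostSpec(per_patient_override=65.06)
    )
    personnel_sessions: float = 2.0
    session_cost_eur: float = 25.55
    daily_wage: float = 24.53

    def __post_init__(self) -> None:
        if self.horizon_years <= 0:
            raise TrialDataError("horizon must be positive")
        if not 0 < self.perturbation < 1:
            raise TrialDataError("perturbation must lie in (0, 1)")
        if self.bootstrap_B < 1:
            raise TrialDataError("bootstrap_B must be >= 1")
        if self.population not in POPULATIONS:
            raise TrialDataError(f"unknown population {self.population!r}")

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["criteria"] = [asdict(c) for c in self.criteria]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        raw = dict(raw)
        if "criteria" in raw:
            raw["criteria"] = [
                c if isinstance(c, ResponderCriterion) else ResponderCriterion(**c)
                for c in raw["criteria"]
            ]
        if "capital" in raw and not isinstance(raw["capital"], CapitalCostSpec):
            raw["capital"] = CapitalCostSpec(**raw["capital"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(Path(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
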