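"""Costing from a social perspective, in 2018 euros.

Four components per participant:

* direct healthcare — resource-use counts priced with the unit-cost table
* capital — the web platform, annualised with the equivalent annual cost
  (EAC) method and shared across the patients served (intervention arm only)
* personnel — the two face-to-face psychologist sessions (intervention only)
* indirect — productivity losses by the human-capital approach:
  sick-leave days x daily wage

SDs of totals are taken over participant-level totals; per-patient constant
components have SD 0 by construction. Medication costs are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trial_data import TrialData, TrialDataError


@dataclass(frozen=True)
class CapitalCostSpec:
    """Parameters of the equivalent-annual-cost calculation.

    If ``per_patient_override`` is set it takes precedence over the annuity
    computation — used when only the final per-patient figure is known.
    """

    total_cost: float = 0.0
    annual_rate: float = 0.03
    asset_life_years: float = 5.0
    patients_served_per_period: int = 1
    duration_years: float = 0.5
    per_patient_override: Optional[float] = None


@dataclass(frozen=True)
class CostBreakdown:
    """Per-arm mean (SD) costs by component and their additive total."""

    arm: str
    n: int
    healthcare_mean: float
    healthcare_sd: float
    capital_per_patient: float
    personnel_per_patient: float
    indirect_mean: float
    indirect_sd: float
    total_mean: float
    total_sd: float

    def component_means(self) -> dict[str, float]:
        return {
            "healthcare": self.healthcare_mean,
            "capital": self.capital_per_patient,
            "personnel": self.personnel_per_patient,
            "indirect": self.indirect_mean,
        }


def direct_healthcare_cost(resource_use: pd.DataFrame, unit_costs: pd.Series) -> pd.Series:
    """Sum count x unit price per participant.

    ``resource_use`` is the long-format table; returns a Series indexed by
    participant id (participants absent from the table are *not* listed —
    absence means zero consumption and is filled in by the caller).
    """
    if len(resource_use) == 0:
        return pd.Series(dtype=float)
    unknown = set(resource_use["category"]) - set(unit_costs.index)
    if unknown:
        raise TrialDataError(f"unpriced resource categories: {sorted(unknown)}")
    if (resource_use["count"] < 0).any():
        raise TrialDataError("negative resource-use count")
    priced = resource_use["count"].to_numpy() * unit_costs.reindex(
        resource_use["category"]
    ).to_numpy()
    return pd.Series(priced).groupby(resource_use["id"].to_numpy()).sum()


def equivalent_annual_cost(spec: CapitalCostSpec) -> float:
    """Per-patient capital cost via the annuity factor K*r / (1-(1+r)^-L).

    The annual figure is scaled to the treatment duration and shared across
    the patients served in that period. At r -> 0 the EAC tends to the
    straight-line K/L.
    """
    if spec.per_patient_override is not None:
        return float(spec.per_patient_override)
    if spec.asset_life_years <= 0:
        raise TrialDataError("asset life must be positive")
    if spec.patients_served_per_period <= 0:
        raise TrialDataError("patients served must be positive")
    if spec.annual_rate < 0:
        raise TrialDataError("annual rate must be nonnegative")
    K, r, L = spec.total_cost, spec.annual_rate, spec.asset_life_years
    if r == 0:
        eac = K / L
    else:
        eac = K * r / (1.0 - (1.0 + r) ** (-L))
    return eac * spec.duration_years / spec.patients_served_per_period


def personnel_cost(sessions: float, cost_per_session: float) -> float:
    """Face-to-face intervention personnel cost: sessions x price."""
    if sessions < 0 or cost_per_session < 0:
        raise TrialDataError("sessions and session cost must be nonnegative")
    return sessions * cost_per_session


def indirect_cost(sick_leave_days, daily_wage: float):
    """Human-capital productivity loss: days absent x daily wage."""
    if daily_wage < 0:
        raise TrialDataError("daily wage must be nonnegative")
    days = np.asarray(sick_leave_days, dtype=float)
    if (days < 0).any():
        raise TrialDataError("sick-leave days must be nonnegative")
    out = days * daily_wage
    return float(out) if out.ndim == 0 else out


def participant_costs(trial: TrialData, config) -> pd.DataFrame:
    """Per-participant component costs, indexed by id.

    Columns: healthcare, capital, personnel, indirect, total. Intervention-only
    components (capital, personnel) are zero in the control arm.
    """
    ids = trial.ids()
    arm = trial.arm_of()
    hc = direct_healthcare_cost(trial.resource_use, trial.unit_costs)
    hc = hc.reindex(ids, fill_value=0.0)

    is_iv = (arm.reindex(ids) == "intervention").to_numpy()
    capital = np.where(is_iv, equivalent_annual_cost(config.capital), 0.0)
    personnel = np.where(
        is_iv, personnel_cost(config.personnel_sessions, config.session_cost_eur), 0.0
    )

    days = trial.indirect.set_index("id")["sick_leave_days"].reindex(ids, fill_value=0.0)
    ind = indirect_cost(days.to_numpy(), config.daily_wage)

    frame = pd.DataFrame(
        {
            "healthcare": hc.to_numpy(dtype=float),
            "capital": capital,
            "personnel": personnel,
            "indirect": ind,
        },
        index=pd.Index(ids, name="id"),
    )
    frame["total"] = frame.sum(axis=1)
    return frame


def arm_total_cost(
    trial: TrialData, arm: str, config, ids: Optional[Sequence] = None
) -> CostBreakdown:
    """Aggregate one arm's participant costs into a CostBreakdown.

    ``ids`` restricts the population (e.g. the complete cases of one
    outcome); it must be a subset of the arm.
    """
    arm_members = trial.arm_ids(arm)
    if ids is None:
        ids = arm_members
    else:
        stray = set(ids) - set(arm_members)
        if stray:
            raise TrialDataError(f"ids not in arm {arm!r}: {sorted(map(str, stray))}")
        ids = list(ids)
    if not ids:
        raise TrialDataError(f"empty population for arm {arm!r}")
    pc = participant_costs(trial, config).loc[ids]

    def _sd(col: str) -> float:
        return float(pc[col].std(ddof=1)) if len(pc) > 1 else 0.0

    return CostBreakdown(
        arm=arm,
        n=len(pc),
        healthcare_mean=float(pc["healthcare"].mean()),
        healthcare_sd=_sd("healthcare"),
        capital_per_patient=float(pc["capital"].mean()),
        personnel_per_patient=float(pc["personnel"].mean()),
        indirect_mean=float(pc["indirect"].mean()),
        indirect_sd=_sd("indirect"),
        total_mean=float(pc["total"].mean()),
        total_sd=_sd("total"),
    )
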