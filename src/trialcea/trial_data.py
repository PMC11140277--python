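"""Participant-level trial data: containers, CSV schemas, validation.

The analysis operates on five flat tables that mirror the CSV interchange
schemas:

``participants``
    one row per participant: ``id, arm, sex, age, modules_completed``
``outcomes``
    long format, one row per participant-visit: ``id, visit_time_years,
    phq9, hba1c, utility`` (empty cell = missing, never imputed on read)
``resource_use``
    long format: ``id, category, count`` over the 6-month costing window
``unit_costs``
    ``category, unit_price_eur`` (2018 euros)
``indirect``
    ``id, sick_leave_days``

Missing outcome values are carried as NaN and stay missing through every
stage; per-outcome complete-case selection happens downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ARMS = ("intervention", "control")

#: canonical healthcare resource categories (rows of the unit-cost table)
RESOURCE_CATEGORIES = (
    "pc_physician",
    "pc_nurse",
    "pc_physician_home",
    "pc_nurse_home",
    "endocrinology",
    "mental_health",
    "emergency",
    "hospitalization_day",
)

PHQ9_RANGE = (0.0, 27.0)
HBA1C_RANGE = (3.0, 20.0)
UTILITY_RANGE = (-0.6, 1.0)


class TrialDataError(ValueError):
    """Raised when input tables violate the documented schemas."""


@dataclass
class TrialData:
    """Validated bundle of participant-level tables plus the unit-cost table.

    ``unit_costs`` is a Series indexed by resource category holding the
    unit price in euros.
    """

    participants: pd.DataFrame
    outcomes: pd.DataFrame
    resource_use: pd.DataFrame
    unit_costs: pd.Series
    indirect: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.indirect is None:
            self.indirect = pd.DataFrame({"id": [], "sick_leave_days": []})
        self.validate()

    # -- accessors -------------------------------------------------------
    def ids(self) -> pd.Index:
        return pd.Index(self.participants["id"])

    def arm_ids(self, arm: str) -> list:
        if arm not in ARMS:
            raise TrialDataError(f"unknown arm {arm!r}; expected one of {ARMS}")
        sel = self.participants.loc[self.participants["arm"] == arm, "id"]
        return list(sel)

    def arm_of(self) -> pd.Series:
        return self.participants.set_index("id")["arm"]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        p = self.participants
        for col in ("id", "arm"):
            if col not in p.columns:
                raise TrialDataError(f"participants table lacks column {col!r}")
        dup = p["id"][p["id"].duplicated()]
        if len(dup):
            raise TrialDataError(f"duplicate participant id(s): {sorted(set(dup))}")
        bad_arm = set(p["arm"]) - set(ARMS)
        if bad_arm:
            raise TrialDataError(f"unknown arm label(s): {sorted(bad_arm)}")

        uc = self.unit_costs
        if (uc < 0).any():
            neg = list(uc.index[uc < 0])
            raise TrialDataError(f"negative unit price for categories: {neg}")

        ru = self.resource_use
        if len(ru):
            unknown = set(ru["category"]) - set(uc.index)
            if unknown:
                raise TrialDataError(
                    f"resource-use categories missing from unit-cost table: "
                    f"{sorted(unknown)}"
                )
            if (ru["count"] < 0).any():
                raise TrialDataError("negative resource-use count")
            orphans = set(ru["id"]) - set(p["id"])
            if orphans:
                raise TrialDataError(f"resource use for unknown participant(s): {sorted(orphans)}")

        out = self.outcomes
        if len(out):
            orphans = set(out["id"]) - set(p["id"])
            if orphans:
                raise TrialDataError(f"outcomes for unknown participant(s): {sorted(orphans)}")
            for pid, grp in out.groupby("id"):
                t = grp["visit_time_years"].to_numpy()
                if len(t) and (t[0] != 0 or np.any(np.diff(t) <= 0)):
                    raise TrialDataError(
                        f"visit times for {pid!r} must strictly increase from 0"
                    )
            self._check_range(out, "phq9", PHQ9_RANGE)
            self._check_range(out, "hba1c", HBA1C_RANGE)
            self._check_range(out, "utility", UTILITY_RANGE)

        ind = self.indirect
        if len(ind) and (ind["sick_leave_days"] < 0).any():
            raise TrialDataError("negative sick-leave days")

    @staticmethod
    def _check_range(frame: pd.DataFrame, col: str, bounds: tuple[float, float]) -> None:
        vals = frame[col].dropna()
        bad = vals[(vals < bounds[0]) | (vals > bounds[1])]
        if len(bad):
            raise TrialDataError(
                f"{col} value(s) outside {list(bounds)}: {sorted(bad.unique())[:5]}"
            )

    # -- wide outcome views ---------------------------------------------
    def outcome_wide(self, outcome: str) -> pd.DataFrame:
        """Pivot one outcome to participants x visit-times (NaN = missing)."""
        wide = self.outcomes.pivot(index="id", columns="visit_time_years", values=outcome)
        return wide.reindex(self.participants["id"])


@dataclass(frozen=True)
class ArmSummary:
    """Arm-level aggregates feeding the cost, CEA and CUA tables."""

    arm: str
    n: int
    cost: "object"  # CostBreakdown
    effectiveness: dict
    baseline_utility: float
    qaly: float
    qaly_gained: float
    n_qaly: int


def read_trial(
    participants_path,
    outcomes_path,
    resource_use_path,
    unit_costs_path,
    indirect_path=None,
) -> TrialData:
    """Read and validate the five CSV tables.

    Empty outcome cells are preserved as missing values. An empty
    resource-use file means zero consumption for every participant.
    """
    participants = pd.read_csv(participants_path)
    outcomes = pd.read_csv(outcomes_path)
    resource_use = pd.read_csv(resource_use_path)
    if resource_use.empty:
        resource_use = pd.DataFrame({"id": [], "category": [], "count": []})
    uc_frame = pd.read_csv(unit_costs_path)
    unit_costs = uc_frame.set_index("category")["unit_price_eur"].astype(float)
    indirect = pd.read_csv(indirect_path) if indirect_path is not None else None
    return TrialData(participants, outcomes, resource_use, unit_costs, indirect)


def write_trial(trial: TrialData, out_dir) -> dict[str, Path]:
    """Write the bundle back to CSV; round-trips losslessly via read_trial."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "outcomes": out / "outcomes.csv",
        "resource_use": out / "resource_use.csv",
        "unit_costs": out / "unit_costs.csv",
        "indirect": out / "indirect.csv",
    }
    trial.participants.to_csv(paths["participants"], index=False)
    trial.outcomes.to_csv(paths["outcomes"], index=False)
    trial.resource_use.to_csv(paths["resource_use"], index=False)
    trial.unit_costs.rename("unit_price_eur").rename_axis("category").reset_index().to_csv(
        paths["unit_costs"], index=False
    )
    trial.indirect.to_csv(paths["indirect"], index=False)
    return paths


def summarize_arm(trial: TrialData, arm: str, config) -> ArmSummary:
    """Aggregate one arm: cost breakdown, responder proportions, QALYs.

    Means and SDs are computed over the configured analysis population;
    responder proportions use per-outcome complete cases by default.
    """
    from . import costing, effectiveness, utility_qaly

    ids = trial.arm_ids(arm)
    if not ids:
        raise TrialDataError(f"arm {arm!r} has no participants")
    cost = costing.arm_total_cost(trial, arm, config)
    eff = {
        crit.label: effectiveness.arm_effectiveness(trial, arm, crit, config.population)
        for crit in config.criteria
    }
    q = utility_qaly.participant_qaly(trial, config)
    q_arm = q[q.index.isin(ids)].dropna()
    if len(q_arm):
        baseline_u = float(q_arm["baseline_utility"].mean())
        qaly = float(q_arm["qaly"].mean())
        gained = float(q_arm["qaly_gained"].mean())
    else:
        baseline_u = qaly = gained = float("nan")
    return ArmSummary(
        arm=arm,
        n=len(ids),
        cost=cost,
        effectiveness=eff,
        baseline_utility=baseline_u,
        qaly=qaly,
        qaly_gained=gained,
        n_qaly=int(len(q_arm)),
    )
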