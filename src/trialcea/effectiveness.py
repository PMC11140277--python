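"""Responder classification and arm-level effectiveness proportions.

A responder criterion is either an absolute reduction (baseline minus
follow-up of at least ``threshold`` points) or a relative reduction of at
least a fraction ``threshold`` of baseline. Thresholds are inclusive: a
change exactly equal to the threshold counts as response — the standard
responder convention.

Notes on the default criteria:

* the 50% PHQ-9 criterion is a *relative* reduction from baseline;
* the HbA1c criterion is an *absolute* reduction of 0.5 percentage points
  of HbA1c (the diabetes-trial MCID convention), not a 0.5% relative drop.

Evaluability is per-criterion complete case by default: a participant needs
both the baseline and the end-of-horizon measurement of that outcome. The
alternative ``itt_locf`` population carries the last observation forward and
evaluates everyone with a baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trial_data import TrialData, TrialDataError

OUTCOMES = ("phq9", "hba1c")
KINDS = ("absolute_reduction", "relative_reduction")
POPULATIONS = ("complete_case", "itt_locf")


@dataclass(frozen=True)
class ResponderCriterion:
    outcome: str
    kind: str
    threshold: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise TrialDataError(f"unknown outcome {self.outcome!r}")
        if self.kind not in KINDS:
            raise TrialDataError(f"unknown criterion kind {self.kind!r}")
        if self.threshold <= 0:
            raise TrialDataError("criterion threshold must be positive")
        if not self.label:
            object.__setattr__(self, "label", self._default_label())

    def _default_label(self) -> str:
        if self.kind == "absolute_reduction":
            return f"{self.outcome}_minus_{self.threshold:g}"
        return f"{self.outcome}_minus_{100 * self.threshold:g}pct"


#: the four base-case criteria: PHQ-9 drops of >=3 and >=5 points, a >=50%
#: relative PHQ-9 reduction, and a >=0.5-point HbA1c reduction
DEFAULT_CRITERIA = (
    ResponderCriterion("phq9", "absolute_reduction", 3.0),
    ResponderCriterion("phq9", "absolute_reduction", 5.0),
    ResponderCriterion("phq9", "relative_reduction", 0.5),
    ResponderCriterion("hba1c", "absolute_reduction", 0.5),
)


@dataclass(frozen=True)
class EffectivenessResult:
    criterion: ResponderCriterion
    arm: str
    n_evaluable: int
    n_responders: int

    @property
    def proportion(self) -> float:
        return self.n_responders / self.n_evaluable


def is_responder(baseline: float, followup: float, criterion: ResponderCriterion):
    """Classify one participant; returns None when not evaluable.

    Relative criteria are undefined at baseline 0 (flagged as None, the
    participant drops out of the denominator).
    """
    if baseline is None or followup is None or np.isnan(baseline) or np.isnan(followup):
        return None
    change = baseline - followup
    if criterion.kind == "absolute_reduction":
        return bool(change >= criterion.threshold)
    if baseline <= 0:
        return None
    return bool(change / baseline >= criterion.threshold)


def response_table(
    trial: TrialData,
    criterion: ResponderCriterion,
    population: str = "complete_case",
    horizon: float = 0.5,
) -> pd.DataFrame:
    """Per-participant response status for one criterion.

    Returns a frame indexed by id with columns ``evaluable`` (bool) and
    ``responder`` (bool, False when not evaluable).
    """
    if population not in POPULATIONS:
        raise TrialDataError(f"unknown population {population!r}")
    wide = trial.outcome_wide(criterion.outcome)
    if 0.0 not in wide.columns:
        raise TrialDataError("no baseline visit in outcomes table")
    baseline = wide[0.0]
    if population == "complete_case":
        if horizon not in wide.columns:
            raise TrialDataError(f"no visit at horizon {horizon}")
        followup = wide[horizon]
    else:  # itt_locf: last observed value, baseline carried forward if needed
        followup = wide.ffill(axis=1).iloc[:, -1]

    rows = {}
    for pid in wide.index:
        status = is_responder(baseline.loc[pid], followup.loc[pid], criterion)
        rows[pid] = {"evaluable": status is not None, "responder": bool(status)}
    return pd.DataFrame.from_dict(rows, orient="index")


def arm_effectiveness(
    trial: TrialData,
    arm: str,
    criterion: ResponderCriterion,
    population: str = "complete_case",
    horizon: float = 0.5,
) -> EffectivenessResult:
    """Responder proportion over the evaluable participants of one arm."""
    table = response_table(trial, criterion, population, horizon)
    ids = trial.arm_ids(arm)
    sub = table.loc[table.index.isin(ids)]
    ev = sub[sub["evaluable"]]
    if len(ev) == 0:
        raise TrialDataError(
            f"no evaluable participants in arm {arm!r} for {criterion.label}"
        )
    return EffectivenessResult(
        criterion=criterion,
        arm=arm,
        n_evaluable=int(len(ev)),
        n_responders=int(ev["responder"].sum()),
    )


def evaluable_ids(
    trial: TrialData,
    arm: str,
    criterion: ResponderCriterion,
    population: str = "complete_case",
    horizon: float = 0.5,
) -> list:
    """Ids of the arm members in the criterion's analysis population."""
    table = response_table(trial, criterion, population, horizon)
    ids = set(trial.arm_ids(arm))
    return [pid for pid in table.index[table["evaluable"]] if pid in ids]
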