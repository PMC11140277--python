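"""Univariate +/-20% sensitivity analysis with tornado ordering.

Each scenario multiplies ONE of the evaluation's main components by
1 - p or 1 + p (default p = 0.2) in BOTH arms simultaneously and recomputes
the incremental ratio through the same arithmetic as the base case:

* ``healthcare_costs`` — each arm's mean direct healthcare cost
* ``intervention_direct_costs`` — capital + personnel overhead (zero in the
  comparator arm, so effectively an intervention-arm shift)
* ``indirect_costs`` — each arm's mean productivity loss
* ``effectiveness_phq9`` / ``effectiveness_hba1c`` — each arm's responder
  proportion for the matching outcome, capped at 1.0
* ``qalys`` — each arm's mean (gained) QALY

A component that does not enter a given outcome (e.g. ``qalys`` for a
PHQ-9 ICER) leaves that ratio at its base value, giving a zero-width
tornado bar. Factor 1 is the identity on every ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .trial_data import TrialDataError

COMPONENTS = (
    "healthcare_costs",
    "intervention_direct_costs",
    "indirect_costs",
    "effectiveness_phq9",
    "effectiveness_hba1c",
    "qalys",
)

_COST_KEYS = ("healthcare_costs", "intervention_direct_costs", "indirect_costs")
_EFFECT_KEY = {"phq9": "effectiveness_phq9", "hba1c": "effectiveness_hba1c", "qaly": "qalys"}


@dataclass(frozen=True)
class OutcomeBase:
    """Base-case summary of one outcome, ready to perturb.

    ``costs_*`` map the three cost components to the arm's mean value over
    that outcome's analysis population.
    """

    label: str
    outcome_kind: str  # phq9 | hba1c | qaly
    effect_intervention: float
    effect_control: float
    costs_intervention: dict = field(hash=False)
    costs_control: dict = field(hash=False)
    effect_cap: Optional[float] = None  # 1.0 for proportions, None for QALYs

    def base_ratio(self) -> float:
        return perturb_and_recompute(self, COMPONENTS[0], 1.0)


@dataclass(frozen=True)
class SensitivityScenario:
    component: str
    direction: str  # low | high
    factor: float
    ratio: float


@dataclass(frozen=True)
class TornadoEntry:
    component: str
    low: float
    base: float
    high: float

    @property
    def width(self) -> float:
        return abs(self.high - self.low)


def _capped(value: float, cap: Optional[float]) -> float:
    return value if cap is None else min(value, cap)


def perturb_and_recompute(base: OutcomeBase, component: str, factor: float) -> float:
    """ICER/ICUR after scaling one component by ``factor`` in both arms."""
    if component not in COMPONENTS:
        raise TrialDataError(f"unknown sensitivity component {component!r}")
    ci = dict(base.costs_intervention)
    cc = dict(base.costs_control)
    ei, ec = base.effect_intervention, base.effect_control
    if component in _COST_KEYS:
        ci[component] = ci.get(component, 0.0) * factor
        cc[component] = cc.get(component, 0.0) * factor
    elif component == _EFFECT_KEY[base.outcome_kind]:
        ei = _capped(ei * factor, base.effect_cap)
        ec = _capped(ec * factor, base.effect_cap)
    delta_cost = sum(ci.values()) - sum(cc.values())
    delta_effect = ei - ec
    if delta_effect == 0:
        return float("nan")
    return delta_cost / delta_effect


def scenarios(
    base: OutcomeBase, component: str, perturbation: float = 0.2
) -> tuple[SensitivityScenario, SensitivityScenario]:
    lo_f, hi_f = 1.0 - perturbation, 1.0 + perturbation
    return (
        SensitivityScenario(component, "low", lo_f, perturb_and_recompute(base, component, lo_f)),
        SensitivityScenario(component, "high", hi_f, perturb_and_recompute(base, component, hi_f)),
    )


def tornado(
    base: OutcomeBase,
    components: Sequence[str] = COMPONENTS,
    perturbation: float = 0.2,
) -> list[TornadoEntry]:
    """One entry per component, widest range first (ties alphabetical)."""
    if not components:
        raise TrialDataError("tornado needs at least one component")
    base_ratio = base.base_ratio()
    entries = []
    for comp in components:
        lo, hi = scenarios(base, comp, perturbation)
        entries.append(TornadoEntry(comp, low=lo.ratio, base=base_ratio, high=hi.ratio))
    return sorted(entries, key=lambda e: (-e.width, e.component))


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    """Plotting-ready table: component, low, base, high, width."""
    return pd.DataFrame(
        [
            {"component": e.component, "low": e.low, "base": e.base, "high": e.high, "width": e.width}
            for e in entries
        ]
    )
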