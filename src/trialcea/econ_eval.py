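"""Incremental ratios, dominance, plane quadrants, bootstrap intervals.

Conventions:

* the cost-effectiveness plane puts incremental effect on x and incremental
  cost on y; NE = more effective & more costly, SE = more effective &
  cheaper, SW = less effective & cheaper, NW = less effective & costlier;
* strict dominance only: SE means the intervention dominates, NW means the
  comparator dominates, NE/SW need a ratio to judge;
* a point on either axis belongs to no quadrant ("on_axis") and a zero
  incremental effect leaves the ratio undefined (NaN);
* in the SW quadrant the ratio is still reported but flagged — there it
  reads as savings forgone per unit of effect lost, not a price paid;
* confidence intervals are nonparametric percentile bootstrap intervals,
  resampling participants within arm. The bootstrap is the field default
  for right-skewed cost data; intervals are reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np

INTERVENTION_DOMINANT = "intervention_dominant"
COMPARATOR_DOMINANT = "comparator_dominant"
NO_DOMINANCE = "none"

QUADRANTS = ("NE", "SE", "SW", "NW")
ON_AXIS = "on_axis"


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_effect: float
    ratio: float  # NaN when delta_effect == 0
    dominance: str
    quadrant: str
    southwest_flag: bool = False
    ci_delta_cost: Optional[Tuple[float, float]] = None
    ci_delta_effect: Optional[Tuple[float, float]] = None

    @property
    def ratio_defined(self) -> bool:
        return not math.isnan(self.ratio)


def cer(cost: float, effect: float) -> float:
    """Average (within-arm) cost-effectiveness ratio; NaN when effect <= 0."""
    if effect <= 0:
        return float("nan")
    return cost / effect


def plane_quadrant(delta_effect: float, delta_cost: float) -> str:
    if delta_effect == 0 or delta_cost == 0:
        return ON_AXIS
    if delta_effect > 0:
        return "NE" if delta_cost > 0 else "SE"
    return "NW" if delta_cost > 0 else "SW"


def dominance_status(delta_cost: float, delta_effect: float) -> str:
    if delta_effect > 0 and delta_cost < 0:
        return INTERVENTION_DOMINANT
    if delta_effect < 0 and delta_cost > 0:
        return COMPARATOR_DOMINANT
    return NO_DOMINANCE


def incremental_analysis(
    cost_a: float,
    effect_a: float,
    cost_b: float,
    effect_b: float,
    ci_delta_cost: Optional[Tuple[float, float]] = None,
    ci_delta_effect: Optional[Tuple[float, float]] = None,
) -> IncrementalResult:
    """Incremental comparison of strategy a (intervention) vs b (comparator).

    The ratio delta_cost / delta_effect is the ICER (cost per additional
    responder, with effects as proportions) or the ICUR (cost per QALY).
    """
    dc = cost_a - cost_b
    de = effect_a - effect_b
    ratio = float("nan") if de == 0 else dc / de
    quad = plane_quadrant(de, dc)
    return IncrementalResult(
        delta_cost=dc,
        delta_effect=de,
        ratio=ratio,
        dominance=dominance_status(dc, de),
        quadrant=quad,
        southwest_flag=quad == "SW",
        ci_delta_cost=ci_delta_cost,
        ci_delta_effect=ci_delta_effect,
    )


def bootstrap_ci(
    data,
    statistic: Callable,
    B: int,
    seed=None,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap interval for ``statistic(data)``.

    ``data`` is an array or DataFrame of participant rows; rows are
    resampled with replacement. ``seed`` may be an int or a Generator.
    Degenerate data yields a zero-width interval.
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(data) if not hasattr(data, "iloc") else data
    n = len(data)
    if n == 0:
        raise ValueError("cannot bootstrap an empty sample")
    idx = rng.integers(0, n, size=(B, n))
    stats = np.empty(B)
    take = (lambda i: data.iloc[i]) if hasattr(data, "iloc") else (lambda i: data[i])
    for b in range(B):
        stats[b] = statistic(take(idx[b]))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def two_sample_bootstrap_ci(
    data_a,
    data_b,
    statistic: Callable,
    B: int,
    seed=None,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile interval for statistic(sample_a, sample_b).

    Participants are resampled independently within each arm, preserving
    the two arm sizes.
    """
    rng = np.random.default_rng(seed)
    na, nb = len(data_a), len(data_b)
    take_a = (lambda i: data_a.iloc[i]) if hasattr(data_a, "iloc") else (lambda i: data_a[i])
    take_b = (lambda i: data_b.iloc[i]) if hasattr(data_b, "iloc") else (lambda i: data_b[i])
    stats = np.empty(B)
    for b in range(B):
        ia = rng.integers(0, na, size=na)
        ib = rng.integers(0, nb, size=nb)
        stats[b] = statistic(take_a(ia), take_b(ib))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
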