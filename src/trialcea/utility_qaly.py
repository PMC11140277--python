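"""Utilities to QALYs over the trial horizon, with baseline adjustment.

QALYs are the trapezoidal area under the utility trajectory u(t) from 0 to
the horizon (linear interpolation between visits; a missing interior visit
simply interpolates across the gap). No discounting: the horizon is below
one year.

Because the arms can start from different utility levels, the headline
quantity is the baseline-adjusted QALY gain

    Q_gain = Q - u0 * T

i.e. the area above the flat line a participant would have traced had their
baseline utility persisted. A regression-based baseline adjustment would be
a possible extension; the closed-form version is what this package
implements.

The instrument side (SF-12 and its eight dimensions) is deliberately kept
behind a pluggable mapping registry: the default ``passthrough`` mapping
consumes a precomputed utility column, and any published tariff can be
registered without touching the pipeline.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trial_data import TrialData, TrialDataError, UTILITY_RANGE

_MAPPINGS: dict[str, Callable] = {}


def register_utility_mapping(name: str, fn: Callable) -> None:
    """Register an instrument-profile -> utility-index mapping."""
    _MAPPINGS[name] = fn


def utility_mapping(name: str) -> Callable:
    if name not in _MAPPINGS:
        raise TrialDataError(
            f"no utility mapping {name!r} registered; known: {sorted(_MAPPINGS)}"
        )
    return _MAPPINGS[name]


def _passthrough(utility: float) -> float:
    if np.isnan(utility):
        return utility
    lo, hi = UTILITY_RANGE
    if not lo <= utility <= hi:
        raise TrialDataError(f"utility {utility} outside index range {list(UTILITY_RANGE)}")
    return float(utility)


register_utility_mapping("passthrough", _passthrough)


def qaly_auc(times: Sequence[float], utilities: Sequence[float], horizon: float) -> float:
    """Trapezoidal QALY over [0, horizon].

    The trajectory must cover both endpoints; no extrapolation beyond the
    last visit. Missing interior values may be dropped by the caller before
    the call (linear interpolation across the gap is then implicit).
    """
    t = np.asarray(times, dtype=float)
    u = np.asarray(utilities, dtype=float)
    keep = ~np.isnan(u)
    t, u = t[keep], u[keep]
    if len(t) < 2 or t[0] != 0:
        raise TrialDataError("trajectory must start at time 0 with >=2 visits")
    if np.any(np.diff(t) <= 0):
        raise TrialDataError("visit times must strictly increase")
    if horizon > t[-1]:
        raise TrialDataError(
            f"horizon {horizon} beyond last visit {t[-1]}; no extrapolation"
        )
    u_h = float(np.interp(horizon, t, u))
    inside = t < horizon
    tt = np.append(t[inside], horizon)
    uu = np.append(u[inside], u_h)
    return float(np.trapezoid(uu, tt))


def qaly_gained(qaly: float, baseline_utility: float, horizon: float) -> float:
    """Baseline-adjusted QALY gain: Q - u0 * T."""
    return qaly - baseline_utility * horizon


def participant_qaly(trial: TrialData, config) -> pd.DataFrame:
    """Per-participant baseline utility, QALY and QALY gained.

    Indexed by id; rows are NaN for participants without both the baseline
    and the end-of-horizon utility (the QALY complete cases).
    """
    mapping = utility_mapping(config.utility_mapping)
    wide = trial.outcome_wide("utility").map(mapping)
    horizon = config.horizon_years
    out = pd.DataFrame(
        index=wide.index, columns=["baseline_utility", "qaly", "qaly_gained"], dtype=float
    )
    times = np.array(wide.columns, dtype=float)
    for pid, row in wide.iterrows():
        u = row.to_numpy(dtype=float)
        if np.isnan(u[0]) or np.isnan(u[times == horizon]).all():
            continue
        q = qaly_auc(times, u, horizon)
        out.loc[pid] = [u[0], q, qaly_gained(q, u[0], horizon)]
    return out
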