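"""Synthetic two-arm trials: a stochastic generator and a deterministic
benchmark dataset.

``generate_trial`` draws participant-level data with the statistical
structure the analysis assumes: truncated-normal PHQ-9 / HbA1c / utility
trajectories, dropout, per-outcome missingness, and right-skewed
zero-inflated lognormal costs (the published cost summaries show SD >= mean,
which demands a point mass at zero plus heavy right skew). Truncated-normal
and zero-inflated-lognormal parameters are moment-matched so configured
means and SDs are the means and SDs actually generated.

``benchmark_trial`` is NOT sampled: it is a fixed dataset constructed by
deterministic arithmetic so that every arm-level aggregate — component cost
means and SDs, per-outcome complete-case cost means, responder counts,
baseline utilities and mean QALYs — equals the published base case of the
web-based depression-in-diabetes trial this package models (22 intervention
vs 27 control participants). It is the reference input for end-to-end
verification of the whole pipeline.

Fixture conventions worth knowing:

* each participant's healthcare spend is carried as a (possibly fractional)
  visit count in a single resource category; only the priced total matters
  to the pipeline;
* sick-leave days may be fractional (days = indirect cost / daily wage);
* responder denominators (13/16 for PHQ-9, 12/14 for HbA1c) are the unique
  integer reconstructions of the published percentages and are a fixture
  convention, not observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trial_data import ARMS, TrialData, TrialDataError

# --------------------------------------------------------------------------
# default unit-cost table (regional public prices, 2018 euros)
# --------------------------------------------------------------------------

DEFAULT_UNIT_COSTS = pd.Series(
    {
        "pc_physician": 38.87,
        "pc_nurse": 23.20,
        "pc_physician_home": 57.97,
        "pc_nurse_home": 34.66,
        "endocrinology": 70.17,
        "mental_health": 92.30,
        "emergency": 142.11,
        "hospitalization_day": 415.48,
    },
    name="unit_price_eur",
)

DAILY_WAGE_2018 = 24.53  # minimum interprofessional wage per day, euros


# --------------------------------------------------------------------------
# stochastic generator
# --------------------------------------------------------------------------


@dataclass
class TrialGeneratorConfig:
    """Study conditions for the stochastic generator.

    Defaults emulate the modelled trial: arm sizes 22/27, dropout 8/22 and
    9/27, moderate baseline depression (PHQ-9 12.71 +/- 3.60 truncated to
    the 5-19 inclusion window), baseline HbA1c 7.16% / 7.78%, and
    per-category cost targets equal to the published healthcare-cost
    summaries. ``cost_model`` maps category -> arm -> (mean, sd, p_zero)
    in euros; ``sick_leave`` is (mean, sd, p_zero) in days.
    """

    n_intervention: int = 22
    n_control: int = 27
    dropout: dict = field(
        default_factory=lambda: {"intervention": 8 / 22, "control": 9 / 27}
    )
    #: extra probability that a non-dropout still misses one measurement
    #: (HbA1c draws require a blood sample, hence the higher rate)
    missing_extra: dict = field(
        default_factory=lambda: {"phq9": 0.05, "hba1c": 0.15, "utility": 0.05}
    )
    phq9_baseline: tuple = (12.71, 3.60)
    phq9_bounds: tuple = (5.0, 19.0)
    phq9_change: dict = field(
        default_factory=lambda: {"intervention": (-5.5, 4.0), "control": (-2.3, 3.5)}
    )
    hba1c_baseline: dict = field(
        default_factory=lambda: {"intervention": (7.16, 1.0), "control": (7.78, 1.0)}
    )
    hba1c_bounds: tuple = (5.0, 12.0)
    hba1c_change: dict = field(
        default_factory=lambda: {"intervention": (-0.25, 0.5), "control": (-0.05, 0.5)}
    )
    utility_baseline: tuple = (0.59, 0.18)
    utility_bounds: tuple = (-0.6, 1.0)
    #: annual utility drift (slope of u(t)) per arm: (mean, sd)
    utility_drift: dict = field(
        default_factory=lambda: {"intervention": (0.2568, 0.25), "control": (0.0764, 0.25)}
    )
    cost_model: dict = field(
        default_factory=lambda: {
            "pc_physician": {
                "intervention": (248.08, 364.24, 0.20),
                "control": (248.59, 398.31, 0.20),
            },
            "pc_nurse": {
                "intervention": (32.29, 82.74, 0.60),
                "control": (23.14, 42.73, 0.60),
            },
            "pc_physician_home": {
                "intervention": (0.0, 0.0, 1.0),
                "control": (23.98, 95.92, 0.90),
            },
            "pc_nurse_home": {
                "intervention": (0.0, 0.0, 1.0),
                "control": (5.64, 22.57, 0.90),
            },
            "endocrinology": {
                "intervention": (21.75, 54.26, 0.60),
                "control": (21.40, 46.00, 0.60),
            },
            "mental_health": {
                "intervention": (30.15, 80.83, 0.70),
                "control": (7.13, 28.53, 0.70),
            },
            "emergency": {
                "intervention": (55.47, 73.04, 0.50),
                "control": (27.04, 78.45, 0.50),
            },
            "hospitalization_day": {
                "intervention": (0.0, 0.0, 1.0),
                "control": (0.0, 0.0, 1.0),
            },
        }
    )
    sick_leave: dict = field(
        default_factory=lambda: {
            "intervention": (0.0, 0.0, 1.0),
            "control": (2.514, 10.056, 0.85),
        }
    )
    unit_costs: pd.Series = field(default_factory=lambda: DEFAULT_UNIT_COSTS.copy())
    visit_times: tuple = (0.0, 0.25, 0.5)


def _truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) so the truncated normal has the target moments."""
    if sd == 0:
        return mean, 0.0

    def moments(x):
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        dist = stats.truncnorm(a, b, loc=mu, scale=sigma)
        return [dist.mean() - mean, dist.std() - sd]

    sol = optimize.root(moments, [mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise TrialDataError(
            f"cannot moment-match truncated normal ({mean}, {sd}) on [{lo}, {hi}]"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _sample_truncnorm(rng, n, mean, sd, lo, hi):
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = _truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma).rvs(size=n, random_state=rng)


def zero_inflated_lognormal_params(mean: float, sd: float, p_zero: float, name: str = ""):
    """(mu, sigma) of the nonzero lognormal part matching the target moments.

    Infeasible when the requested SD is too small to accommodate the zero
    mass; the error names the offending category.
    """
    if not 0 <= p_zero < 1:
        raise TrialDataError(f"zero-inflation probability out of [0,1) for {name!r}")
    m1 = mean / (1.0 - p_zero)
    ey2 = (sd**2 + mean**2) / (1.0 - p_zero)
    if ey2 <= m1**2:
        raise TrialDataError(
            f"infeasible moment match for {name!r}: SD {sd} too small for "
            f"zero-inflation {p_zero} at mean {mean}"
        )
    sigma2 = np.log(ey2 / m1**2)
    mu = np.log(m1) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _sample_zi_lognormal(rng, n, mean, sd, p_zero, name=""):
    if mean == 0:
        return np.zeros(n)
    if sd == 0:
        base = np.full(n, mean / (1.0 - p_zero))
    else:
        mu, sigma = zero_inflated_lognormal_params(mean, sd, p_zero, name)
        base = rng.lognormal(mu, sigma, size=n)
    zero = rng.random(n) < p_zero
    return np.where(zero, 0.0, base)


def generate_trial(config: Optional[TrialGeneratorConfig] = None, seed=None) -> TrialData:
    """Draw one synthetic trial; byte-identical datasets for equal seeds."""
    config = config or TrialGeneratorConfig()
    rng = np.random.default_rng(seed)
    t3, t6 = config.visit_times[1], config.visit_times[2]

    participants, outcomes, resource, indirect = [], [], [], []
    for arm, n in (("intervention", config.n_intervention), ("control", config.n_control)):
        prefix = "I" if arm == "intervention" else "C"
        ids = [f"{prefix}{k + 1:02d}" for k in range(n)]
        dropout = rng.random(n) < config.dropout[arm]

        phq0 = _sample_truncnorm(rng, n, *config.phq9_baseline, *config.phq9_bounds)
        dphq = rng.normal(*config.phq9_change[arm], size=n)
        hb0 = _sample_truncnorm(rng, n, *config.hba1c_baseline[arm], *config.hba1c_bounds)
        dhb = rng.normal(*config.hba1c_change[arm], size=n)
        u0 = _sample_truncnorm(rng, n, *config.utility_baseline, *config.utility_bounds)
        drift = rng.normal(*config.utility_drift[arm], size=n)

        miss = {
            k: rng.random((n, 2)) < config.missing_extra[k] for k in ("phq9", "hba1c", "utility")
        }
        costs = {
            cat: _sample_zi_lognormal(rng, n, *spec[arm], name=cat)
            for cat, spec in config.cost_model.items()
        }
        days = _sample_zi_lognormal(rng, n, *config.sick_leave[arm], name="sick_leave")

        mods = np.where(
            dropout,
            rng.integers(0, 4, size=n),
            np.where(rng.random(n) < 0.6, 10, rng.integers(4, 10, size=n)),
        )
        for i, pid in enumerate(ids):
            participants.append(
                {
                    "id": pid,
                    "arm": arm,
                    "sex": "female" if rng.random() < (0.73 if arm == "intervention" else 0.44) else "male",
                    "age": int(np.clip(rng.normal(57.3, 8.6), 30, 80)),
                    "modules_completed": int(mods[i]) if arm == "intervention" else np.nan,
                }
            )
            phq = [phq0[i], np.clip(phq0[i] + dphq[i] / 2, 0, 27), np.clip(phq0[i] + dphq[i], 0, 27)]
            hba = [hb0[i], hb0[i] + dhb[i] / 2, hb0[i] + dhb[i]]
            uti = [u0[i], u0[i] + drift[i] * t3, u0[i] + drift[i] * t6]
            hba = list(np.clip(hba, 3.0, 20.0))
            uti = list(np.clip(uti, -0.6, 1.0))
            phq = [round(v) for v in phq]
            for j, t in enumerate(config.visit_times):
                gone = dropout[i] and j > 0
                outcomes.append(
                    {
                        "id": pid,
                        "visit_time_years": t,
                        "phq9": np.nan if gone or (j > 0 and miss["phq9"][i, j - 1]) else phq[j],
                        "hba1c": np.nan if gone or (j > 0 and miss["hba1c"][i, j - 1]) else hba[j],
                        "utility": np.nan if gone or (j > 0 and miss["utility"][i, j - 1]) else uti[j],
                    }
                )
            for cat in config.cost_model:
                if costs[cat][i] > 0:
                    resource.append(
                        {
                            "id": pid,
                            "category": cat,
                            "count": costs[cat][i] / config.unit_costs[cat],
                        }
                    )
            indirect.append({"id": pid, "sick_leave_days": days[i]})

    return TrialData(
        participants=pd.DataFrame(participants),
        outcomes=pd.DataFrame(outcomes),
        resource_use=pd.DataFrame(resource, columns=["id", "category", "count"]),
        unit_costs=config.unit_costs.astype(float),
        indirect=pd.DataFrame(indirect),
    )


# --------------------------------------------------------------------------
# deterministic benchmark dataset
# --------------------------------------------------------------------------

# Healthcare cost vectors solved in closed form so that, per arm: the mean
# and SD match the published cost table; the PHQ-9 complete cases (first 13
# intervention / first 16 control ids) have the arm's full mean; and the
# HbA1c complete cases (first 12 intervention / last 14 control ids) have
# the published subsample means (365.43 + 116.16 = 481.59 and 571.53).
_IG_HEALTHCARE = (
    [203.31982359935864] * 11  # I01-I11
    + [2148.641940407055]  # I12 (one high consumer)
    + [655.59]  # I13
    + [225.63982359935864] * 8  # I14-I21
    + [1684.631411205131]  # I22
)

_CG_HEALTHCARE = (
    [44.34098561722749] * 11  # C01-C11
    + [1295.1462555983337]  # C12 (high consumer)
    + [262.72508568532714]  # C13 (the long-sick-leave participant)
    + [995.682605642279] * 3  # C14-C16
    + [245.8535291025152] * 10  # C17-C26
    + [2146.174708974846]  # C27 (high consumer)
)

# indirect productivity-loss euros (control arm only, as published)
_CG_INDIRECT = {
    **{f"C{k:02d}": 3.976182215656777 for k in range(1, 7)},
    "C13": 1231.5707236328974,
    "C14": 409.66218307316217,
}

# zero-sum perturbations keeping arm means exact while varying participants
_PAIR = (0.02, -0.02)


def _paired(base: float, n_pairs: int, extra_zero: bool, step: float):
    vals = []
    for _ in range(n_pairs):
        vals.extend([base + step, base - step])
    if extra_zero:
        vals.append(base)
    return vals


def benchmark_trial() -> TrialData:
    """Deterministic 22-vs-27 dataset reproducing the published base case."""
    ig_ids = [f"I{k:02d}" for k in range(1, 23)]
    cg_ids = [f"C{k:02d}" for k in range(1, 28)]

    # --- participants ---------------------------------------------------
    ig_mods = [10] * 9 + [1] + [7, 5, 8, 6, 3, 2, 4, 2] + [0, 0, 0, 0]
    participants = pd.DataFrame(
        {
            "id": ig_ids + cg_ids,
            "arm": ["intervention"] * 22 + ["control"] * 27,
            "sex": (["female"] * 16 + ["male"] * 6) + (["female"] * 12 + ["male"] * 15),
            "age": [50 + (k % 17) for k in range(22)] + [48 + (k % 19) for k in range(27)],
            "modules_completed": ig_mods + [np.nan] * 27,
        }
    )

    # --- outcome trajectories ------------------------------------------
    # PHQ-9 evaluable: I01-I13 / C01-C16. Responder layout (inclusive
    # thresholds): strong = both the 5-point and 50% criteria; moderate =
    # 3-point only.
    phq = {}
    for pid in ig_ids[:7]:
        phq[pid] = (14, 9, 6)  # strong: -8 points, 57%
    for pid in ig_ids[7:10]:
        phq[pid] = (13, 11, 9)  # moderate: -4 points, 31%
    for pid in ig_ids[10:13]:
        phq[pid] = (12, 12, 11)  # non-responder: -1 point
    for pid in ig_ids[13:]:
        phq[pid] = (12, np.nan, np.nan)
    for pid in cg_ids[:2]:
        phq[pid] = (12, 8, 5)  # strong: -7 points, 58%
    for pid in cg_ids[2:5]:
        phq[pid] = (12, 10, 8)  # moderate: -4 points, 33%
    for pid in cg_ids[5:16]:
        phq[pid] = (11, 11, 10)  # non-responder
    for pid in cg_ids[16:]:
        phq[pid] = (11, np.nan, np.nan)

    # HbA1c evaluable: I01-I12 / C14-C27; responders 1/12 and 2/14.
    hba = {}
    hba["I01"] = (7.8, 7.5, 7.2)  # -0.6 point responder
    for pid in ig_ids[1:12]:
        hba[pid] = (7.2, 7.1, 7.0)
    for pid in ig_ids[12:]:
        hba[pid] = (7.2, np.nan, np.nan)
    for pid in cg_ids[:13]:
        hba[pid] = (7.8, np.nan, np.nan)
    for pid in cg_ids[13:15]:
        hba[pid] = (8.0, 7.7, 7.4)  # -0.6 point responders
    for pid in cg_ids[15:]:
        hba[pid] = (7.8, 7.7, 7.6)

    # Utilities: linear trajectories u(t) = u0 + d*t, complete for every
    # participant, so the cost-utility population is the full arm and its
    # cost components are exactly the arm-level cost table. Means solved
    # from the published arm QALYs: mean AUC = u0/2 + d/8 over the 6-month
    # horizon.
    uti = {}
    ig_u0 = _paired(0.5898, 11, False, 0.02)
    ig_d = _paired(0.2568, 11, False, 0.04)
    for pid, u0, d in zip(ig_ids, ig_u0, ig_d):
        uti[pid] = (u0, u0 + 0.25 * d, u0 + 0.5 * d)
    cg_u0 = _paired(0.5935, 13, True, 0.02)
    cg_d = _paired(0.0764, 13, True, 0.03)
    for pid, u0, d in zip(cg_ids, cg_u0, cg_d):
        uti[pid] = (u0, u0 + 0.25 * d, u0 + 0.5 * d)

    outcomes = []
    for pid in ig_ids + cg_ids:
        for j, t in enumerate((0.0, 0.25, 0.5)):
            outcomes.append(
                {
                    "id": pid,
                    "visit_time_years": t,
                    "phq9": phq[pid][j],
                    "hba1c": hba[pid][j],
                    "utility": uti[pid][j],
                }
            )

    # --- costs ----------------------------------------------------------
    price = DEFAULT_UNIT_COSTS["pc_physician"]
    resource = [
        {"id": pid, "category": "pc_physician", "count": euros / price}
        for pid, euros in zip(ig_ids + cg_ids, _IG_HEALTHCARE + _CG_HEALTHCARE)
    ]
    indirect = pd.DataFrame(
        {
            "id": ig_ids + cg_ids,
            "sick_leave_days": [0.0] * 22
            + [_CG_INDIRECT.get(pid, 0.0) / DAILY_WAGE_2018 for pid in cg_ids],
        }
    )

    return TrialData(
        participants=participants,
        outcomes=pd.DataFrame(outcomes),
        resource_use=pd.DataFrame(resource),
        unit_costs=DEFAULT_UNIT_COSTS.copy(),
        indirect=indirect,
    )
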