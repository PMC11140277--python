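"""Pipeline driver: costing -> effectiveness -> QALYs -> incremental
analysis -> sensitivity, emitted as tidy tables.

Cost means feeding each comparison are taken over that outcome's analysis
population (the per-outcome complete cases by default), which is why the
HbA1c comparison carries different arm costs than the PHQ-9 comparisons.
Effects are carried as proportions (displayed as percentage points) for the
CEA — the ICER is then cost per additional responder — and as QALYs for
the CUA.

All tables keep full precision; display rounding (money to cents, percents
to 2 decimals, QALYs to 4) happens only in the CSV writer.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import costing, effectiveness, sensitivity, utility_qaly
from .config import AnalysisConfig
from .econ_eval import cer, incremental_analysis, two_sample_bootstrap_ci, bootstrap_ci
from .trial_data import TrialData, TrialDataError

logger = logging.getLogger("trialcea")

__version__ = "0.1.0"


@dataclass
class ReportBundle:
    """Every table of one pipeline run plus the metadata to recompute it."""

    cost_table: pd.DataFrame
    cea_table: pd.DataFrame
    cua_table: pd.DataFrame
    tornado: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "cost_table": self.cost_table.to_dict(orient="records"),
            "cea_table": self.cea_table.to_dict(orient="records"),
            "cua_table": self.cua_table.to_dict(orient="records"),
            "tornado": {k: v.to_dict(orient="records") for k, v in self.tornado.items()},
            "metadata": self.metadata,
        }


def _cost_rows(trial: TrialData, config: AnalysisConfig) -> pd.DataFrame:
    rows = []
    for arm in ("intervention", "control"):
        bd = costing.arm_total_cost(trial, arm, config)
        rows.append(
            {
                "arm": arm,
                "n": bd.n,
                "healthcare_mean": bd.healthcare_mean,
                "healthcare_sd": bd.healthcare_sd,
                "capital_per_patient": bd.capital_per_patient,
                "personnel_per_patient": bd.personnel_per_patient,
                "indirect_mean": bd.indirect_mean,
                "indirect_sd": bd.indirect_sd,
                "total_mean": bd.total_mean,
                "total_sd": bd.total_sd,
            }
        )
    return pd.DataFrame(rows)


def _arm_cost_components(trial, config, arm, ids) -> dict:
    bd = costing.arm_total_cost(trial, arm, config, ids=ids)
    return {
        "healthcare_costs": bd.healthcare_mean,
        "intervention_direct_costs": bd.capital_per_patient + bd.personnel_per_patient,
        "indirect_costs": bd.indirect_mean,
    }


def _comparison(
    trial,
    config,
    label: str,
    outcome_kind: str,
    ids_iv: list,
    ids_cg: list,
    effect_iv: float,
    effect_cg: float,
    effect_values: Optional[dict],
    effect_cap: Optional[float],
    seed,
) -> tuple[list[dict], sensitivity.OutcomeBase]:
    """Three table rows (arm, arm, incremental) plus the perturbable base."""
    pc = costing.participant_costs(trial, config)
    cost_iv = pc.loc[ids_iv, "total"]
    cost_cg = pc.loc[ids_cg, "total"]
    comp_iv = _arm_cost_components(trial, config, "intervention", ids_iv)
    comp_cg = _arm_cost_components(trial, config, "control", ids_cg)

    B = config.bootstrap_B
    rng = np.random.default_rng(seed)
    ci_cost_iv = bootstrap_ci(cost_iv.to_numpy(), np.mean, B, rng)
    ci_cost_cg = bootstrap_ci(cost_cg.to_numpy(), np.mean, B, rng)
    if effect_values is not None:
        ev_iv = np.asarray(effect_values["intervention"], dtype=float)
        ev_cg = np.asarray(effect_values["control"], dtype=float)
        ci_eff_iv = bootstrap_ci(ev_iv, np.mean, B, rng)
        ci_eff_cg = bootstrap_ci(ev_cg, np.mean, B, rng)
        ci_dc = two_sample_bootstrap_ci(
            cost_iv.to_numpy(), cost_cg.to_numpy(), lambda a, b: a.mean() - b.mean(), B, rng
        )
        ci_de = two_sample_bootstrap_ci(ev_iv, ev_cg, lambda a, b: a.mean() - b.mean(), B, rng)
    else:
        ci_eff_iv = ci_eff_cg = ci_dc = ci_de = (float("nan"), float("nan"))

    inc = incremental_analysis(
        float(cost_iv.mean()), effect_iv, float(cost_cg.mean()), effect_cg,
        ci_delta_cost=ci_dc, ci_delta_effect=ci_de,
    )
    rows = [
        {
            "outcome": label,
            "row": "intervention",
            "n": len(ids_iv),
            "cost": float(cost_iv.mean()),
            "cost_ci_low": ci_cost_iv[0],
            "cost_ci_high": ci_cost_iv[1],
            "effect": effect_iv,
            "effect_ci_low": ci_eff_iv[0],
            "effect_ci_high": ci_eff_iv[1],
            "ratio": cer(float(cost_iv.mean()), effect_iv),
            "quadrant": "",
            "dominance": "",
        },
        {
            "outcome": label,
            "row": "control",
            "n": len(ids_cg),
            "cost": float(cost_cg.mean()),
            "cost_ci_low": ci_cost_cg[0],
            "cost_ci_high": ci_cost_cg[1],
            "effect": effect_cg,
            "effect_ci_low": ci_eff_cg[0],
            "effect_ci_high": ci_eff_cg[1],
            "ratio": cer(float(cost_cg.mean()), effect_cg),
            "quadrant": "",
            "dominance": "",
        },
        {
            "outcome": label,
            "row": "incremental",
            "n": len(ids_iv) + len(ids_cg),
            "cost": inc.delta_cost,
            "cost_ci_low": ci_dc[0],
            "cost_ci_high": ci_dc[1],
            "effect": inc.delta_effect,
            "effect_ci_low": ci_de[0],
            "effect_ci_high": ci_de[1],
            "ratio": inc.ratio,
            "quadrant": inc.quadrant,
            "dominance": inc.dominance,
        },
    ]
    base = sensitivity.OutcomeBase(
        label=label,
        outcome_kind=outcome_kind,
        effect_intervention=effect_iv,
        effect_control=effect_cg,
        costs_intervention=comp_iv,
        costs_control=comp_cg,
        effect_cap=effect_cap,
    )
    return rows, base


def run_pipeline(trial: TrialData, config: Optional[AnalysisConfig] = None) -> ReportBundle:
    """Execute every stage on one trial and collect the report tables."""
    config = config or AnalysisConfig()
    seeds = np.random.SeedSequence(config.seed).spawn(len(config.criteria) + 2)

    logger.info("costing: %d participants", len(trial.participants))
    cost_table = _cost_rows(trial, config)

    cea_rows, bases = [], {}
    for crit, seed in zip(config.criteria, seeds):
        res_iv = effectiveness.arm_effectiveness(trial, "intervention", crit, config.population)
        res_cg = effectiveness.arm_effectiveness(trial, "control", crit, config.population)
        ids_iv = effectiveness.evaluable_ids(trial, "intervention", crit, config.population)
        ids_cg = effectiveness.evaluable_ids(trial, "control", crit, config.population)
        table = effectiveness.response_table(trial, crit, config.population)
        effect_values = {
            "intervention": table.loc[ids_iv, "responder"].astype(float).to_numpy(),
            "control": table.loc[ids_cg, "responder"].astype(float).to_numpy(),
        }
        rows, base = _comparison(
            trial, config, crit.label, crit.outcome,
            ids_iv, ids_cg, res_iv.proportion, res_cg.proportion,
            effect_values, 1.0, seed,
        )
        cea_rows.extend(rows)
        bases[crit.label] = base
        logger.info(
            "effectiveness %s: %d/%d vs %d/%d", crit.label,
            res_iv.n_responders, res_iv.n_evaluable, res_cg.n_responders, res_cg.n_evaluable,
        )
    cea_table = pd.DataFrame(cea_rows)

    # --- cost-utility ---------------------------------------------------
    q = utility_qaly.participant_qaly(trial, config)
    cua_rows = []
    for col, label, seed in (
        ("qaly", "qaly", seeds[-2]),
        ("qaly_gained", "qaly_gained", seeds[-1]),
    ):
        sub = q.dropna()
        ids_iv = [i for i in trial.arm_ids("intervention") if i in sub.index]
        ids_cg = [i for i in trial.arm_ids("control") if i in sub.index]
        if not ids_iv or not ids_cg:
            raise TrialDataError("no QALY-evaluable participants in one arm")
        effect_values = {
            "intervention": sub.loc[ids_iv, col].to_numpy(),
            "control": sub.loc[ids_cg, col].to_numpy(),
        }
        rows, base = _comparison(
            trial, config, label, "qaly",
            ids_iv, ids_cg,
            float(sub.loc[ids_iv, col].mean()), float(sub.loc[ids_cg, col].mean()),
            effect_values, None, seed,
        )
        cua_rows.extend(rows)
        bases[label] = base
        logger.info("utility_qaly %s: %d vs %d evaluable", label, len(ids_iv), len(ids_cg))
    cua_table = pd.DataFrame(cua_rows)

    tornado_tables = {
        label: sensitivity.tornado_frame(
            sensitivity.tornado(base, perturbation=config.perturbation)
        )
        for label, base in bases.items()
    }

    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True, default=str)
    metadata = {
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_participants": int(len(trial.participants)),
    }
    return ReportBundle(cost_table, cea_table, cua_table, tornado_tables, metadata)


def _rounded(frame: pd.DataFrame, spec: dict) -> pd.DataFrame:
    out = frame.copy()
    for col, nd in spec.items():
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce").round(nd)
    return out


def write_bundle(bundle: ReportBundle, out_dir) -> dict[str, Path]:
    """Write CSV tables (display-rounded) and a full-precision JSON bundle.

    Everything is computed before the first byte is written, so a failing
    stage never leaves partial output behind.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    money = {c: 2 for c in ("cost", "cost_ci_low", "cost_ci_high", "ratio", "low", "base", "high", "width")}
    cost_round = {c: 2 for c in bundle.cost_table.columns if c not in ("arm", "n")}
    paths = {"json": out / "report.json"}
    with open(paths["json"], "w") as fh:
        json.dump(bundle.to_json_dict(), fh, indent=2, default=str)
    paths["cost"] = out / "cost_table.csv"
    _rounded(bundle.cost_table, cost_round).to_csv(paths["cost"], index=False)

    cea = bundle.cea_table.copy()
    if len(cea):
        for c in ("effect", "effect_ci_low", "effect_ci_high"):
            cea[c] = 100.0 * pd.to_numeric(cea[c], errors="coerce")  # percentage points
        cea = _rounded(cea, {**money, "effect": 2, "effect_ci_low": 2, "effect_ci_high": 2})
    paths["cea"] = out / "cea_table.csv"
    cea.to_csv(paths["cea"], index=False)

    cua = _rounded(bundle.cua_table, {**money, "effect": 4, "effect_ci_low": 4, "effect_ci_high": 4})
    paths["cua"] = out / "cua_table.csv"
    cua.to_csv(paths["cua"], index=False)

    for label, tf in bundle.tornado.items():
        p = out / f"tornado_{label}.csv"
        paths[f"tornado_{label}"] = p
        _rounded(tf, money).to_csv(p, index=False)
    return paths
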