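import numpy as np
import pandas as pd
import pytest

import trialcea as tc
from trialcea.trial_data import TrialDataError


def test_benchmark_arm_sizes(benchmark):
    assert len(benchmark.arm_ids("intervention")) == 22
    assert len(benchmark.arm_ids("control")) == 27
    assert len(benchmark.participants) == 49


def test_round_trip_is_lossless(tmp_path, benchmark):
    """Write/read preserves every value including missing markers."""
    paths = tc.write_trial(benchmark, tmp_path)
    back = tc.read_trial(
        paths["participants"], paths["outcomes"], paths["resource_use"],
        paths["unit_costs"], paths["indirect"],
    )
    pd.testing.assert_frame_equal(back.participants, benchmark.participants, check_dtype=False)
    pd.testing.assert_frame_equal(back.outcomes, benchmark.outcomes, check_dtype=False)
    pd.testing.assert_frame_equal(back.resource_use, benchmark.resource_use, check_dtype=False)
    pd.testing.assert_frame_equal(back.indirect, benchmark.indirect, check_dtype=False)
    pd.testing.assert_series_equal(
        back.unit_costs, benchmark.unit_costs, check_dtype=False, check_names=False
    )
    # missingness preserved, not imputed
    assert back.outcomes["phq9"].isna().sum() == benchmark.outcomes["phq9"].isna().sum() > 0


def test_empty_resource_use_means_zero_consumption(tmp_path, benchmark):
    paths = tc.write_trial(benchmark, tmp_path)
    empty = tmp_path / "empty_resource_use.csv"
    empty.write_text("id,category,count\n")
    trial = tc.read_trial(
        paths["participants"], paths["outcomes"], empty, paths["unit_costs"], paths["indirect"]
    )
    cfg = tc.AnalysisConfig()
    bd = tc.arm_total_cost(trial, "control", cfg)
    assert bd.healthcare_mean == 0.0


@pytest.mark.parametrize(
    "mutate, match",
    [
        (lambda t: t.resource_use.replace({"pc_physician": "dialysis"}), "dialysis"),
        (lambda t: t.resource_use.assign(count=-1.0), "negative"),
        (lambda t: pd.concat([t.participants, t.participants.iloc[[0]]]), "duplicate"),
    ],
)
def test_validation_rejects_bad_tables(benchmark, mutate, match):
    parts, ru = benchmark.participants.copy(), benchmark.resource_use.copy()
    mutated = mutate(benchmark)
    if "arm" in mutated.columns:
        parts = mutated
    else:
        ru = mutated
    with pytest.raises(TrialDataError, match=match):
        tc.TrialData(parts, benchmark.outcomes.copy(), ru,
                     benchmark.unit_costs.copy(), benchmark.indirect.copy())


def test_negative_unit_price_rejected(benchmark):
    uc = benchmark.unit_costs.copy()
    uc["emergency"] = -1.0
    with pytest.raises(TrialDataError, match="negative unit price"):
        tc.TrialData(benchmark.participants.copy(), benchmark.outcomes.copy(),
                     benchmark.resource_use.copy(), uc, benchmark.indirect.copy())


def test_out_of_range_outcomes_rejected(benchmark):
    out = benchmark.outcomes.copy()
    out.loc[out.index[0], "phq9"] = 31.0
    with pytest.raises(TrialDataError, match="phq9"):
        tc.TrialData(benchmark.participants.copy(), out, benchmark.resource_use.copy(),
                     benchmark.unit_costs.copy(), benchmark.indirect.copy())


def test_summarize_arm_reproduces_cost_table(benchmark, config):
    """Arm summary matches the published intervention-arm aggregates."""
    s = tc.summarize_arm(benchmark, "intervention", config)
    assert s.n == 22
    assert round(s.cost.healthcare_mean, 2) == 387.75
    assert round(s.cost.total_mean, 2) == 503.91
    assert round(s.baseline_utility, 4) == 0.5898
    assert round(s.qaly, 4) == 0.3270
    eff = s.effectiveness["phq9_minus_3"]
    assert (eff.n_responders, eff.n_evaluable) == (10, 13)


def test_summarize_empty_arm_errors(benchmark, config):
    solo = benchmark.participants[benchmark.participants["arm"] == "control"]
    trial = tc.TrialData(
        solo.copy(),
        benchmark.outcomes[benchmark.outcomes["id"].isin(solo["id"])].copy(),
        benchmark.resource_use[benchmark.resource_use["id"].isin(solo["id"])].copy(),
        benchmark.unit_costs.copy(),
        benchmark.indirect[benchmark.indirect["id"].isin(solo["id"])].copy(),
    )
    with pytest.raises(TrialDataError):
        tc.summarize_arm(trial, "intervention", config)


def test_single_participant_sd_is_zero(benchmark, config):
    one = benchmark.arm_ids("control")[:1]
    bd = tc.arm_total_cost(benchmark, "control", config, ids=one)
    assert bd.n == 1 and bd.total_sd == 0.0


def test_generated_cost_mean_matches_configured_moments():
    """Law-of-large-numbers check against the generator's own parameters."""
    gen = tc.TrialGeneratorConfig(
        n_intervention=2, n_control=1000,
        cost_model={"pc_physician": {"intervention": (400.0, 500.0, 0.3),
                                     "control": (400.0, 500.0, 0.3)}},
    )
    trial = tc.generate_trial(gen, seed=11)
    bd = tc.arm_total_cost(trial, "control", tc.AnalysisConfig())
    assert abs(bd.healthcare_mean - 400.0) < 3 * 500.0 / np.sqrt(1000)
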