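import numpy as np
import pytest
from hypothesis import given, strategies as st

import trialcea as tc
from trialcea.effectiveness import ResponderCriterion, evaluable_ids, response_table
from trialcea.trial_data import TrialDataError

ABS3 = ResponderCriterion("phq9", "absolute_reduction", 3.0)
ABS5 = ResponderCriterion("phq9", "absolute_reduction", 5.0)
REL50 = ResponderCriterion("phq9", "relative_reduction", 0.5)
HBA = ResponderCriterion("hba1c", "absolute_reduction", 0.5)


class TestIsResponder:
    @pytest.mark.parametrize(
        "baseline, followup, crit, expected",
        [
            (12, 9, ABS3, True),  # boundary inclusive
            (12, 10, ABS3, False),
            (12, 6, REL50, True),  # 6/12 = 0.50 exactly
            (12, 7, REL50, False),  # 5/12 < 0.50
            (7.8, 7.3, HBA, True),  # boundary inclusive
            (7.8, 7.4, HBA, False),
        ],
    )
    def test_threshold_conventions(self, baseline, followup, crit, expected):
        assert tc.is_responder(baseline, followup, crit) is expected

    def test_missing_value_not_evaluable(self):
        assert tc.is_responder(12.0, np.nan, ABS3) is None

    def test_relative_with_zero_baseline_flagged(self):
        assert tc.is_responder(0.0, 0.0, REL50) is None

    @given(
        baseline=st.floats(min_value=0, max_value=27),
        followup=st.floats(min_value=0, max_value=27),
    )
    def test_absolute_criteria_nest(self, baseline, followup):
        """Every 5-point responder is a 3-point responder."""
        if tc.is_responder(baseline, followup, ABS5):
            assert tc.is_responder(baseline, followup, ABS3)


class TestArmEffectiveness:
    @pytest.mark.parametrize(
        "arm, crit, expected",
        [
            ("intervention", ABS3, (10, 13)),
            ("control", ABS3, (5, 16)),
            ("intervention", ABS5, (7, 13)),
            ("control", ABS5, (2, 16)),
            ("intervention", HBA, (1, 12)),
            ("control", HBA, (2, 14)),
        ],
    )
    def test_benchmark_responder_counts(self, benchmark, arm, crit, expected):
        res = tc.arm_effectiveness(benchmark, arm, crit)
        assert (res.n_responders, res.n_evaluable) == expected

    def test_benchmark_proportions(self, benchmark):
        assert tc.arm_effectiveness(benchmark, "intervention", ABS3).proportion == pytest.approx(
            0.7692, abs=5e-5
        )
        assert tc.arm_effectiveness(benchmark, "control", ABS3).proportion == 5 / 16

    def test_five_point_and_half_reduction_sets_coincide(self, benchmark):
        """The 5-point and 50% criteria pick the same responders here."""
        t5 = response_table(benchmark, ABS5)
        t50 = response_table(benchmark, REL50)
        assert (t5["responder"] == t50["responder"]).all()
        assert (t5["evaluable"] == t50["evaluable"]).all()

    def test_universal_improvement_gives_proportion_one(self, benchmark):
        out = benchmark.outcomes.copy()
        base = out[out["visit_time_years"] == 0].set_index("id")["phq9"]
        final = out["visit_time_years"] == 0.5
        out.loc[final, "phq9"] = (
            out.loc[final, "id"].map(base).to_numpy() - 10.0
        ).clip(0.0)
        trial = tc.TrialData(benchmark.participants.copy(), out,
                             benchmark.resource_use.copy(), benchmark.unit_costs.copy(),
                             benchmark.indirect.copy())
        assert tc.arm_effectiveness(trial, "intervention", ABS3).proportion == 1.0

    def test_record_order_invariance(self, benchmark):
        shuffled = tc.TrialData(
            benchmark.participants.sample(frac=1, random_state=3).reset_index(drop=True),
            benchmark.outcomes.sample(frac=1, random_state=4)
            .sort_values(["id", "visit_time_years"])
            .reset_index(drop=True),
            benchmark.resource_use.copy(), benchmark.unit_costs.copy(),
            benchmark.indirect.copy(),
        )
        for crit in (ABS3, ABS5, HBA):
            for arm in tc.ARMS:
                assert (
                    tc.arm_effectiveness(shuffled, arm, crit).proportion
                    == tc.arm_effectiveness(benchmark, arm, crit).proportion
                )

    def test_no_evaluable_errors(self, benchmark):
        out = benchmark.outcomes.copy()
        out.loc[out["visit_time_years"] == 0.5, "phq9"] = np.nan
        trial = tc.TrialData(benchmark.participants.copy(), out,
                             benchmark.resource_use.copy(), benchmark.unit_costs.copy(),
                             benchmark.indirect.copy())
        with pytest.raises(TrialDataError):
            tc.arm_effectiveness(trial, "intervention", ABS3)

    def test_itt_locf_population_uses_baseline_carry_forward(self, benchmark):
        """LOCF evaluates everyone with a baseline; carried-forward baselines
        cannot respond, so proportions drop relative to complete case."""
        res = tc.arm_effectiveness(benchmark, "intervention", ABS3, population="itt_locf")
        assert res.n_evaluable == 22
        assert res.n_responders == 10

    def test_evaluable_ids_subset_of_arm(self, benchmark):
        ids = evaluable_ids(benchmark, "control", HBA)
        assert len(ids) == 14
        assert set(ids) <= set(benchmark.arm_ids("control"))


def test_invalid_criterion_rejected():
    with pytest.raises(TrialDataError):
        ResponderCriterion("phq9", "absolute_reduction", 0.0)
    with pytest.raises(TrialDataError):
        ResponderCriterion("weight", "absolute_reduction", 1.0)
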