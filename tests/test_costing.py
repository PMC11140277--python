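import pandas as pd
import pytest

import trialcea as tc
from trialcea.costing import CapitalCostSpec
from trialcea.trial_data import TrialDataError


class TestDirectHealthcare:
    def test_multiply_and_sum(self):
        ru = pd.DataFrame(
            {"id": ["p1", "p1"], "category": ["pc_physician", "emergency"], "count": [3, 1]}
        )
        prices = pd.Series({"pc_physician": 50.0, "emergency": 120.0})
        assert tc.direct_healthcare_cost(ru, prices)["p1"] == 270.0

    def test_zero_counts(self):
        ru = pd.DataFrame({"id": ["p1"], "category": ["pc_physician"], "count": [0.0]})
        prices = pd.Series({"pc_physician": 50.0})
        assert tc.direct_healthcare_cost(ru, prices)["p1"] == 0.0

    def test_unpriced_category_errors(self):
        ru = pd.DataFrame({"id": ["p1"], "category": ["dialysis"], "count": [1]})
        with pytest.raises(TrialDataError, match="dialysis"):
            tc.direct_healthcare_cost(ru, pd.Series({"pc_physician": 50.0}))

    def test_control_arm_mean(self, benchmark, config):
        bd = tc.arm_total_cost(benchmark, "control", config)
        assert round(bd.healthcare_mean, 2) == 356.94


class TestEquivalentAnnualCost:
    def test_zero_rate_limit_is_straight_line(self):
        K, L = 130123.0, 5.0
        spec = CapitalCostSpec(K, 1e-9, L, 1, duration_years=1.0)
        assert abs(tc.equivalent_annual_cost(spec) - K / L) < 1e-6 * K / L

    def test_annuity_factor_against_payment_formula(self):
        # independent oracle: loan-payment form PMT = K r (1+r)^L / ((1+r)^L - 1)
        K, r, L = 130123.0, 0.03, 5.0
        pmt = K * r * (1 + r) ** L / ((1 + r) ** L - 1)
        spec = CapitalCostSpec(K, r, L, 1, duration_years=1.0)
        assert tc.equivalent_annual_cost(spec) == pytest.approx(pmt, rel=1e-12)

    def test_per_patient_override_takes_precedence(self):
        spec = CapitalCostSpec(999999.0, 0.1, 2.0, 10, per_patient_override=65.06)
        assert tc.equivalent_annual_cost(spec) == 65.06

    def test_invalid_life_errors(self):
        with pytest.raises(TrialDataError):
            tc.equivalent_annual_cost(CapitalCostSpec(1000.0, 0.03, 0.0, 1))


def test_personnel_cost_product():
    assert tc.personnel_cost(0, 25.55) == 0.0
    assert tc.personnel_cost(2, 25.55) == pytest.approx(51.10)


def test_indirect_cost_human_capital():
    assert tc.indirect_cost(0, 30.0) == 0.0
    assert tc.indirect_cost(10, 30.0) == pytest.approx(300.0)
    with pytest.raises(TrialDataError):
        tc.indirect_cost(-1, 30.0)


class TestArmTotals:
    def test_intervention_total_is_component_sum(self, benchmark, config):
        bd = tc.arm_total_cost(benchmark, "intervention", config)
        assert round(bd.total_mean, 2) == 503.91
        assert bd.total_mean == pytest.approx(
            bd.healthcare_mean + bd.capital_per_patient + bd.personnel_per_patient
            + bd.indirect_mean,
            abs=1e-9,
        )

    def test_control_total(self, benchmark, config):
        bd = tc.arm_total_cost(benchmark, "control", config)
        assert round(bd.total_mean, 2) == 418.61
        assert bd.capital_per_patient == 0.0 and bd.personnel_per_patient == 0.0

    def test_all_zero_components(self, benchmark, config):
        trial = tc.TrialData(
            benchmark.participants.copy(),
            benchmark.outcomes.copy(),
            benchmark.resource_use.iloc[0:0].copy(),
            benchmark.unit_costs.copy(),
            benchmark.indirect.assign(sick_leave_days=0.0),
        )
        cfg = tc.AnalysisConfig(
            capital=CapitalCostSpec(per_patient_override=0.0), session_cost_eur=0.0
        )
        bd = tc.arm_total_cost(trial, "intervention", cfg)
        assert bd.total_mean == 0.0 and bd.total_sd == 0.0

    @pytest.mark.parametrize("k", [0.5, 2.0, 7.3])
    def test_homogeneity_in_prices_and_wages(self, benchmark, k):
        """Scaling every price, wage and fixed cost by k scales all money by k."""
        base_cfg = tc.AnalysisConfig()
        scaled = tc.TrialData(
            benchmark.participants.copy(), benchmark.outcomes.copy(),
            benchmark.resource_use.copy(), benchmark.unit_costs * k,
            benchmark.indirect.copy(),
        )
        cfg = tc.AnalysisConfig(
            capital=CapitalCostSpec(per_patient_override=65.06 * k),
            session_cost_eur=25.55 * k,
            daily_wage=24.53 * k,
        )
        for arm in tc.ARMS:
            b0 = tc.arm_total_cost(benchmark, arm, base_cfg)
            b1 = tc.arm_total_cost(scaled, arm, cfg)
            assert b1.total_mean == pytest.approx(k * b0.total_mean, rel=1e-9)
            assert b1.total_sd == pytest.approx(k * b0.total_sd, rel=1e-9)

    def test_ids_outside_arm_rejected(self, benchmark, config):
        with pytest.raises(TrialDataError):
            tc.arm_total_cost(benchmark, "intervention", config, ids=["C01"])
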