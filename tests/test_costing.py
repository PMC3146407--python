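import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesacea import MarkovCEModel
from mesacea.costing import (
    build_state_cost_table,
    discount_factor,
    drug_cost_per_cycle,
    outpatient_cost_per_cycle,
    prednisolone_taper_cost,
)
from mesacea.parameters import ASACOL, MEZAVANT, ParameterError
from mesacea.states import HealthState


class TestDrugCosts:
    def test_standard_dose_mezavant(self, base_bundle):
        got = drug_cost_per_cycle(
            base_bundle.arms[MEZAVANT], HealthState.ACTIVE_1L, base_bundle.costs, 56
        )
        assert got == pytest.approx(2 * 1.13 * 56)  # 126.56

    def test_high_dose_asacol(self, base_bundle):
        got = drug_cost_per_cycle(
            base_bundle.arms[ASACOL],
            HealthState.ACTIVE_1L_HIGH,
            base_bundle.costs,
            56,
        )
        assert got == pytest.approx(12 * 0.44 * 56)  # 295.68

    def test_zero_duration_costs_nothing(self, base_bundle):
        for arm in base_bundle.arms.values():
            assert (
                drug_cost_per_cycle(arm, HealthState.ACTIVE_1L, base_bundle.costs, 0)
                == 0.0
            )

    def test_non_drug_state_returns_zero(self, base_bundle):
        got = drug_cost_per_cycle(
            base_bundle.arms[MEZAVANT], HealthState.SURGERY, base_bundle.costs, 56
        )
        assert got == 0.0

    def test_second_line_includes_steroid_taper(self, base_bundle):
        with_pred = drug_cost_per_cycle(
            base_bundle.arms[MEZAVANT], HealthState.ACTIVE_2L, base_bundle.costs, 56
        )
        assert with_pred == pytest.approx(4 * 1.13 * 56 + 7.875)


class TestPrednisoloneTaper:
    def test_weekly_taper_sum(self, base_bundle):
        # 8 weekly daily doses 40..5 mg, 7 days each, at 0.25 EUR / 40 mg
        assert prednisolone_taper_cost(base_bundle.costs) == pytest.approx(7.875)

    def test_zero_price_zero_cost(self, base_bundle):
        base_bundle.costs.prednisolone_price_per_40mg = 0.0
        assert prednisolone_taper_cost(base_bundle.costs) == 0.0

    def test_linear_in_price(self, base_bundle):
        base = prednisolone_taper_cost(base_bundle.costs)
        base_bundle.costs.prednisolone_price_per_40mg *= 2
        assert prednisolone_taper_cost(base_bundle.costs) == pytest.approx(2 * base)


class TestOutpatientCosts:
    def test_active_state_cycle_cost_rounds_to_printed_value(self, base_bundle):
        assert round(outpatient_cost_per_cycle(base_bundle.costs), 2) == 47.21

    def test_zero_components(self, base_bundle):
        base_bundle.costs.gastro_lump_sum_per_quarter = 0.0
        base_bundle.costs.outpatient_procedures_per_6months = 0.0
        assert outpatient_cost_per_cycle(base_bundle.costs) == 0.0

    def test_quarterly_lump_sum_alone(self, base_bundle):
        base_bundle.costs.outpatient_procedures_per_6months = 0.0
        assert round(outpatient_cost_per_cycle(base_bundle.costs), 2) == 11.63


class TestStateCostTable:
    def test_component_assembly(self, base_bundle):
        table = build_state_cost_table(
            base_bundle.arms[MEZAVANT], base_bundle.costs, base_bundle.config
        )
        a2l = table.total[HealthState.ACTIVE_2L.value]
        assert a2l == pytest.approx(4 * 1.13 * 56 + 7.875 + outpatient_cost_per_cycle(base_bundle.costs))
        assert table.total[HealthState.SURGERY.value] == 3812.55
        assert table.total[HealthState.FAILURE_RELAPSE.value] == 1584.27
        assert table.total[HealthState.DEATH.value] == 0.0

    def test_no_outpatient_cost_outside_active_states(self, base_bundle):
        table = build_state_cost_table(
            base_bundle.arms[ASACOL], base_bundle.costs, base_bundle.config
        )
        for state in ("REMISSION", "POST_SURGERY", "FAILURE_RELAPSE", "SURGERY", "DEATH"):
            assert table.frame.loc[state, "outpatient"] == 0.0

    def test_remission_carries_maintenance_drug_only(self, base_bundle):
        table = build_state_cost_table(
            base_bundle.arms[MEZAVANT], base_bundle.costs, base_bundle.config
        )
        assert table.total["REMISSION"] == pytest.approx(2 * 1.13 * 56)


class TestDiscounting:
    def test_cycle_zero_factor_is_one(self, base_bundle):
        assert discount_factor(base_bundle.config, 0) == 1.0

    def test_zero_rate_never_discounts(self, base_bundle):
        base_bundle.config.annual_discount_rate = 0.0
        assert discount_factor(base_bundle.config, 100) == 1.0

    def test_closed_form_two_year_factor(self, base_bundle):
        # logarithmic identity oracle
        expected = math.exp(-13 * 56 / 365.25 * math.log(1.05))
        assert discount_factor(base_bundle.config, 13) == pytest.approx(
            expected, abs=1e-15
        )

    def test_negative_cycle_rejected(self, base_bundle):
        with pytest.raises(ParameterError):
            discount_factor(base_bundle.config, -1)


class TestCostProperties:
    @given(rate=st.floats(0.0, 0.3))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_discounting_never_increases_total_cost(self, rate):
        model = MarkovCEModel.base_case(annual_discount_rate=rate)
        res = model.fit()
        undiscounted = MarkovCEModel.base_case(annual_discount_rate=0.0).fit()
        for arm in res.arm_results:
            assert (
                res.arm_results[arm].discounted_cost
                <= undiscounted.arm_results[arm].discounted_cost + 1e-9
            )

    def test_zero_prices_mean_zero_cost(self, base_bundle):
        import dataclasses

        for f in dataclasses.fields(base_bundle.costs):
            setattr(base_bundle.costs, f.name, 0.0)
        for arm in base_bundle.arms.values():
            arm.price_per_tablet_eur = 1e-12  # validator requires > 0
        res = MarkovCEModel(base_bundle).fit()
        for arm_res in res.arm_results.values():
            assert arm_res.discounted_cost == pytest.approx(0.0, abs=1e-6)

    def test_total_cost_linear_in_tablet_price(self, base_bundle):
        base_bundle.costs.prednisolone_price_per_40mg = 0.0  # isolate tablet cost
        res0 = MarkovCEModel(base_bundle).fit()
        drug0 = res0.arm_results[MEZAVANT].cost_breakdown["drug"].sum()
        other0 = res0.arm_results[MEZAVANT].discounted_cost - drug0
        b = base_bundle.copy()
        b.arms[MEZAVANT].price_per_tablet_eur *= 3
        res3 = MarkovCEModel(b).fit()
        drug3 = res3.arm_results[MEZAVANT].cost_breakdown["drug"].sum()
        assert drug3 == pytest.approx(3 * drug0, rel=1e-12)
        assert res3.arm_results[MEZAVANT].discounted_cost - drug3 == pytest.approx(
            other0, rel=1e-12
        )

    def test_2010_price_update_preserves_cost_saving(self, base_bundle):
        """Under the April-2010 net prices Mezavant stays cheaper overall.

        Both net tablet prices fell by ~11.5%, so the absolute daily price
        gap shrinks slightly; the cost saving persists but does not widen.
        """
        base_inc = MarkovCEModel(base_bundle).fit().incremental.incremental_cost
        b = base_bundle.copy()
        b.arms[MEZAVANT].price_per_tablet_eur = b.costs.alt_price_mezavant_tablet
        b.arms[ASACOL].price_per_tablet_eur = b.costs.alt_price_asacol_tablet
        alt_inc = MarkovCEModel(b).fit().incremental.incremental_cost
        assert alt_inc < 0
        assert base_inc < 0
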