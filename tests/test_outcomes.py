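import numpy as np
import pytest

from mesacea import run_cohort
from mesacea.cohort import state_space_for
from mesacea.costing import build_state_cost_table, discount_factor
from mesacea.outcomes import (
    DOMINANT,
    DOMINATED,
    EQUIVALENT,
    ICER_LABEL,
    ArmResults,
    compute_qalys,
    count_events,
    days_in_remission,
    incremental_analysis,
)
from mesacea.parameters import ASACOL, MEZAVANT
from mesacea.transitions import build_transition_matrix


def _toy_trace(base_bundle, occupancy_builder, n_cycles=4):
    """CohortTrace with hand-set occupancy (entries left zero)."""
    from mesacea.cohort import CohortTrace

    space = state_space_for(base_bundle.transitions, base_bundle.config)
    occ = np.zeros((n_cycles + 1, space.n_states))
    occupancy_builder(space, occ)
    return CohortTrace(
        arm=MEZAVANT,
        occupancy=occ,
        entries=np.zeros((n_cycles, 8)),
        space=space,
        config=base_bundle.config,
    )


class TestQALYs:
    def test_dead_cohort_accrues_nothing(self, base_bundle):
        trace = _toy_trace(
            base_bundle, lambda sp, occ: occ.__setitem__((slice(None), sp.i_death), 1.0)
        )
        assert compute_qalys(trace, base_bundle.utilities, base_bundle.config) == 0.0

    def test_one_undiscounted_remission_year(self, base_bundle):
        # seven 8-week cycles at 56/365.25 years each ~ 1 model year
        base_bundle.config.annual_discount_rate = 0.0
        trace = _toy_trace(
            base_bundle,
            lambda sp, occ: occ.__setitem__(
                (slice(None), sp.i_remission_start), 1.0
            ),
            n_cycles=7,
        )
        got = compute_qalys(trace, base_bundle.utilities, base_bundle.config)
        assert got == pytest.approx(0.845 * 7 * 56 / 365.25, rel=1e-12)

    def test_matches_brute_force_double_loop(self, base_bundle):
        trace = run_cohort(base_bundle, ASACOL)
        u = base_bundle.utilities
        cfg = base_bundle.config
        expected = 0.0
        for t in range(trace.n_cycles):
            for i in range(trace.space.n_states):
                expected += (
                    trace.occupancy[t, i]
                    * u.for_state(trace.space.logical_of(i))
                    * cfg.cycle_years
                    * discount_factor(cfg, t)
                )
        got = compute_qalys(trace, u, cfg)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_horizon_at_full_utility(self, base_bundle):
        trace = run_cohort(base_bundle, MEZAVANT)
        u = base_bundle.utilities
        u.active = u.severe = u.remission = 1.0
        qalys = compute_qalys(trace, u, base_bundle.config)
        assert qalys <= trace.n_cycles * base_bundle.config.cycle_years + 1e-12
        # with all utilities at 1, QALYs equal discounted life years
        df = sum(
            discount_factor(base_bundle.config, t)
            * (1 - trace.death_occupancy()[t])
            for t in range(trace.n_cycles)
        )
        assert qalys == pytest.approx(df * base_bundle.config.cycle_years, rel=1e-12)


class TestRemissionDays:
    def test_no_remission_no_days(self, base_bundle):
        trace = _toy_trace(
            base_bundle,
            lambda sp, occ: occ.__setitem__((slice(None), sp.i_active_1l), 1.0),
        )
        assert days_in_remission(trace, base_bundle.config) == 0.0

    def test_ten_full_cycles(self, base_bundle):
        trace = _toy_trace(
            base_bundle,
            lambda sp, occ: occ.__setitem__((slice(None), sp.i_remission_start), 1.0),
            n_cycles=10,
        )
        assert days_in_remission(trace, base_bundle.config) == 560.0


class TestEventCounts:
    def test_quiet_trace_has_no_events(self, base_bundle):
        base_bundle.transitions.p_remit_1l[MEZAVANT] = 1.0  # straight to remission
        base_bundle.transitions.p_relapse[MEZAVANT] = 0.0
        trace = run_cohort(base_bundle, MEZAVANT)
        assert count_events(trace) == (0.0, 0.0)

    def test_three_cycle_flows_match_hand_count(self, base_bundle):
        """Inflows into hospitalisation/surgery equal explicit matrix algebra."""
        trace = run_cohort(base_bundle, ASACOL, n_cycles=3)
        space = state_space_for(base_bundle.transitions, base_bundle.config)
        T = build_transition_matrix(
            base_bundle.transitions, base_bundle.arms[ASACOL], base_bundle.config, space
        )
        expected_fail = sum(
            trace.occupancy[t] @ T[:, space.i_failure] for t in range(3)
        )
        expected_surg = sum(
            trace.occupancy[t] @ T[:, space.i_surgery] for t in range(3)
        )
        episodes, surgeries = count_events(trace)
        assert episodes == pytest.approx(expected_fail, rel=1e-12)
        assert surgeries == pytest.approx(expected_surg, rel=1e-12)


def _fake_arm(name, cost, qalys):
    import pandas as pd

    return ArmResults(
        arm=name,
        discounted_cost=cost,
        discounted_qalys=qalys,
        remission_days=0.0,
        inpatient_episodes=0.0,
        surgeries=0.0,
        cost_breakdown=pd.DataFrame(),
    )


class TestIncrementalAnalysis:
    def test_cheaper_and_better_is_dominant_without_icer(self):
        res = incremental_analysis(_fake_arm("A", 4940.0, 3.320), _fake_arm("B", 5564.0, 3.309))
        assert res.label == DOMINANT
        assert res.icer is None
        assert res.incremental_cost == pytest.approx(-624.0)
        assert res.incremental_qalys == pytest.approx(0.011)

    def test_identical_arms_are_equivalent(self):
        res = incremental_analysis(_fake_arm("A", 100.0, 1.0), _fake_arm("B", 100.0, 1.0))
        assert res.label == EQUIVALENT

    def test_icer_simple_division(self):
        res = incremental_analysis(_fake_arm("A", 1100.0, 1.01), _fake_arm("B", 1000.0, 1.0))
        assert res.label == ICER_LABEL
        assert res.icer == pytest.approx(10_000.0)

    def test_costlier_and_worse_is_dominated(self):
        res = incremental_analysis(_fake_arm("A", 200.0, 0.9), _fake_arm("B", 100.0, 1.0))
        assert res.label == DOMINATED

    def test_antisymmetric_under_arm_swap(self):
        a, b = _fake_arm("A", 4940.0, 3.320), _fake_arm("B", 5564.0, 3.309)
        fwd = incremental_analysis(a, b)
        rev = incremental_analysis(b, a)
        assert rev.incremental_cost == -fwd.incremental_cost
        assert rev.incremental_qalys == -fwd.incremental_qalys
        assert {fwd.label, rev.label} == {DOMINANT, DOMINATED}
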