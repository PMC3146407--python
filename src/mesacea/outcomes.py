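"""Outcome measures: QALYs, remission days, events, incremental analysis.

Costs and QALYs accrue on the state occupancy at the start of each cycle
and are discounted with that cycle's factor; the optional half-cycle
correction averages start- and end-of-cycle occupancy instead.  Days in
remission and event counts are reported undiscounted, in natural units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTrace
from .costing import StateCostTable, discount_factors
from .parameters import ModelConfig, ParameterError, UtilitySet
from .states import LOGICAL_STATES, HealthState

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"
ICER_LABEL = "icer"


def _accrual_occupancy(trace: CohortTrace, config: ModelConfig) -> np.ndarray:
    """Occupancy used for per-cycle accrual: start-of-cycle, or the
    start/end average under the half-cycle correction."""
    occ = trace.occupancy
    if config.half_cycle_correction:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def utility_vector(utilities: UtilitySet, trace: CohortTrace) -> np.ndarray:
    utilities.validate()
    space = trace.space
    return np.array(
        [utilities.for_state(space.logical_of(i)) for i in range(space.n_states)]
    )


def compute_qalys(
    trace: CohortTrace, utilities: UtilitySet, config: ModelConfig
) -> float:
    """Discounted quality-adjusted life years of one cohort trace."""
    u = utility_vector(utilities, trace)
    if np.any((u < 0) | (u > 1)):
        raise ParameterError("utilities must lie in [0, 1]")
    occ = _accrual_occupancy(trace, config)
    df = discount_factors(config, trace.n_cycles)
    return float(((occ @ u) * df).sum() * config.cycle_years)


def compute_discounted_cost(
    trace: CohortTrace, cost_table: StateCostTable, config: ModelConfig
) -> float:
    c = cost_table.cost_vector(trace.space)
    occ = _accrual_occupancy(trace, config)
    df = discount_factors(config, trace.n_cycles)
    return float(((occ @ c) * df).sum())


def cost_breakdown(
    trace: CohortTrace, cost_table: StateCostTable, config: ModelConfig
) -> pd.DataFrame:
    """Discounted cost per logical state and component."""
    occ_logical = trace.space.aggregate(_accrual_occupancy(trace, config))
    df = discount_factors(config, trace.n_cycles)
    weights = (occ_logical * df[:, None]).sum(axis=0)  # discounted cycles per state
    out = cost_table.frame.mul(weights, axis=0)
    out["total"] = out.sum(axis=1)
    return out


def days_in_remission(trace: CohortTrace, config: ModelConfig) -> float:
    """Undiscounted days spent in the aggregate remission state."""
    rem = trace.remission_occupancy()[:-1]  # start-of-cycle occupancy
    return float(rem.sum() * config.cycle_length_days)


def count_events(trace: CohortTrace) -> tuple[float, float]:
    """(inpatient episodes, surgeries) per model patient, from entry flows."""
    idx_fail = LOGICAL_STATES.index(HealthState.FAILURE_RELAPSE)
    idx_surg = LOGICAL_STATES.index(HealthState.SURGERY)
    return (
        float(trace.entries[:, idx_fail].sum()),
        float(trace.entries[:, idx_surg].sum()),
    )


@dataclass
class ArmResults:
    """Aggregate outcomes of one treatment arm."""

    arm: str
    discounted_cost: float
    discounted_qalys: float
    remission_days: float
    inpatient_episodes: float
    surgeries: float
    cost_breakdown: pd.DataFrame = field(repr=False)

    def validate(self, horizon_years: float) -> None:
        if self.discounted_qalys > horizon_years + 1e-9:
            raise ParameterError("QALYs exceed the model horizon")
        if min(self.inpatient_episodes, self.surgeries, self.remission_days) < 0:
            raise ParameterError("event counts must be non-negative")


def arm_results(
    trace: CohortTrace,
    cost_table: StateCostTable,
    utilities: UtilitySet,
    config: ModelConfig,
) -> ArmResults:
    episodes, surgeries = count_events(trace)
    return ArmResults(
        arm=trace.arm,
        discounted_cost=compute_discounted_cost(trace, cost_table, config),
        discounted_qalys=compute_qalys(trace, utilities, config),
        remission_days=days_in_remission(trace, config),
        inpatient_episodes=episodes,
        surgeries=surgeries,
        cost_breakdown=cost_breakdown(trace, cost_table, config),
    )


@dataclass
class CEResult:
    """Incremental comparison (intervention minus comparator)."""

    intervention: str
    comparator: str
    incremental_cost: float
    incremental_qalys: float
    label: str
    icer: float | None

    def __str__(self) -> str:  # pragma: no cover - convenience only
        icer = "NA" if self.icer is None else f"{self.icer:,.0f} EUR/QALY"
        return (
            f"{self.intervention} vs {self.comparator}: "
            f"dCost {self.incremental_cost:+,.0f} EUR, "
            f"dQALY {self.incremental_qalys:+.3f} -> {self.label} (ICER {icer})"
        )


def incremental_analysis(
    intervention: ArmResults, comparator: ArmResults, tol: float = 1e-12
) -> CEResult:
    """Classify dominance and compute the ICER where the signs agree.

    Lower cost with at least equal QALYs (or equal cost with higher QALYs)
    is dominance; the ICER is reported only when extra cost buys extra
    QALYs or savings forgo QALYs.
    """
    dc = intervention.discounted_cost - comparator.discounted_cost
    dq = intervention.discounted_qalys - comparator.discounted_qalys
    zero_c, zero_q = abs(dc) <= tol, abs(dq) <= tol
    if zero_c and zero_q:
        label, icer = EQUIVALENT, None
    elif (dc < 0 and dq >= 0) or (zero_c and dq > 0):
        label, icer = DOMINANT, None
    elif (dc > 0 and dq <= 0) or (zero_c and dq < 0):
        label, icer = DOMINATED, None
    elif zero_q:
        # nonzero cost at identical effect: ICER undefined
        label, icer = (DOMINATED if dc > 0 else DOMINANT), None
    else:
        label, icer = ICER_LABEL, dc / dq
    return CEResult(
        intervention=intervention.arm,
        comparator=comparator.arm,
        incremental_cost=dc,
        incremental_qalys=dq,
        label=label,
        icer=icer,
    )
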