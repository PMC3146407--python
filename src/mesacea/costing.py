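"""Per-state per-cycle costs (EUR, German SHI perspective) and discounting.

Cost components per 8-week cycle:

* drug acquisition — tablets/day x net price/tablet x cycle days; the three
  active states are dosed at 2,400 (first line) or 4,800 mg/day (increased
  dose and second line); remission carries the maintenance dose;
* prednisolone taper in second line — 40 mg/day tapered by 5 mg each week;
* outpatient care for active states — quarterly EBM lump sum plus
  six-monthly procedure costs, both scaled to the 8-week cycle;
* DRG lump sums on hospitalisation (without/with surgery), charged per
  cycle of occupancy, which equals once per stay because neither inpatient
  state has a self-loop.

Arithmetic is kept at full floating precision; rounding to cents happens
only in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import CostParameters, ModelConfig, ParameterError, TreatmentArm
from .states import ACTIVE_STATES, LOGICAL_STATES, HealthState, StateSpace

log = logging.getLogger(__name__)

#: daily prednisolone dose (mg) in each week of the second-line taper
PREDNISOLONE_TAPER_MG = (40, 35, 30, 25, 20, 15, 10, 5)

DRUG_STATES = ACTIVE_STATES + (HealthState.REMISSION,)


def drug_cost_per_cycle(
    arm: TreatmentArm,
    state: HealthState,
    costs: CostParameters,
    cycle_length_days: float,
) -> float:
    """Mesalazine (plus second-line steroid) cost for one cycle in ``state``."""
    if state not in DRUG_STATES:
        log.info("state %s carries no drug cost", state.value)
        return 0.0
    if state is HealthState.ACTIVE_1L:
        tablets = arm.tablets_per_day_standard
    elif state is HealthState.REMISSION:
        tablets = arm.tablets_per_day_maintenance
    else:  # increased first-line dose and second line: 4,800 mg/day
        tablets = arm.tablets_per_day_high
    cost = tablets * arm.price_per_tablet_eur * cycle_length_days
    if state is HealthState.ACTIVE_2L:
        cost += prednisolone_taper_cost(costs)
    return cost


def prednisolone_taper_cost(costs: CostParameters) -> float:
    """Cost of the 8-week oral corticosteroid taper (EUR per cycle)."""
    price_per_mg = costs.prednisolone_price_per_40mg / 40.0
    return sum(dose * 7 for dose in PREDNISOLONE_TAPER_MG) * price_per_mg


def outpatient_cost_per_cycle(costs: CostParameters) -> float:
    """Outpatient cost of one 8-week cycle in an active disease state.

    Quarterly gastroenterologist lump sum scaled by 8/13 weeks plus
    six-monthly procedure costs scaled by 8/26 weeks.
    """
    return (
        costs.gastro_lump_sum_per_quarter * 8.0 / 13.0
        + costs.outpatient_procedures_per_6months * 8.0 / 26.0
    )


@dataclass
class StateCostTable:
    """Per-cycle cost of every logical state for one arm, by component."""

    arm: str
    frame: pd.DataFrame  # index: logical state, columns: drug/outpatient/inpatient

    @property
    def total(self) -> pd.Series:
        return self.frame.sum(axis=1)

    def cost_vector(self, space: StateSpace) -> np.ndarray:
        """Expand to the tunnel-expanded state list."""
        totals = self.total
        return np.array(
            [totals[space.logical_of(i).value] for i in range(space.n_states)]
        )

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["total"] = self.total
        out.round(2).to_csv(path)


def build_state_cost_table(
    arm: TreatmentArm, costs: CostParameters, config: ModelConfig
) -> StateCostTable:
    """Assemble the per-state per-cycle cost table for one arm."""
    costs.validate()
    outpatient = outpatient_cost_per_cycle(costs)
    rows = {}
    for state in LOGICAL_STATES:
        drug = (
            drug_cost_per_cycle(arm, state, costs, config.cycle_length_days)
            if state in DRUG_STATES
            else 0.0
        )
        outp = outpatient if state in ACTIVE_STATES else 0.0
        if state is HealthState.FAILURE_RELAPSE:
            inpatient = costs.drg_inpatient_no_surgery
        elif state is HealthState.SURGERY:
            inpatient = costs.drg_inpatient_surgery
        else:
            inpatient = 0.0
        rows[state.value] = {"drug": drug, "outpatient": outp, "inpatient": inpatient}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    return StateCostTable(arm=arm.name, frame=frame)


def discount_factor(config: ModelConfig, cycle_index: int) -> float:
    """Discount factor for cycle ``cycle_index`` at the annual rate."""
    if cycle_index < 0:
        raise ParameterError("cycle_index must be non-negative")
    return (1.0 + config.annual_discount_rate) ** (
        -cycle_index * config.cycle_years
    )


def discount_factors(config: ModelConfig, n_cycles: int) -> np.ndarray:
    k = np.arange(n_cycles)
    return (1.0 + config.annual_discount_rate) ** (-k * config.cycle_years)
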