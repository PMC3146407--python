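"""Cohort iteration: propagate state occupancy through the Markov chain."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import LifeTable, ModelConfig, ParameterBundle, TransitionParameters
from .states import LOGICAL_STATES, HealthState, StateSpace, cycles_per_tunnel_year
from .transitions import build_transition_matrix

CONSERVATION_TOL = 1e-12


class NumericError(RuntimeError):
    pass


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy of one treatment arm.

    Attributes
    ----------
    occupancy
        ``(n_cycles + 1, n_states)`` array over the expanded state list;
        row 0 is the initial distribution (everyone in first-line active
        disease).
    entries
        ``(n_cycles, n_logical)`` new entrants per *logical* state per
        cycle — inflows from other logical states only, so remission
        tunnel advancement and self-loops do not count as events.
    """

    arm: str
    occupancy: np.ndarray
    entries: np.ndarray
    space: StateSpace
    config: ModelConfig

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def occupancy_logical(self) -> np.ndarray:
        return self.space.aggregate(self.occupancy)

    def remission_occupancy(self) -> np.ndarray:
        """Aggregate remission occupancy per cycle (tunnel states summed)."""
        return self.occupancy[:, self.space.remission_slice].sum(axis=1)

    def death_occupancy(self) -> np.ndarray:
        return self.occupancy[:, self.space.i_death]

    def check_conservation(self, tol: float = CONSERVATION_TOL) -> None:
        err = np.abs(self.occupancy.sum(axis=1) - 1.0).max()
        if err > tol:
            raise NumericError(f"occupancy not conserved (max error {err:g})")

    def to_frame(self) -> pd.DataFrame:
        """Logical-state occupancy, one row per cycle."""
        df = pd.DataFrame(
            self.occupancy_logical(), columns=[s.value for s in LOGICAL_STATES]
        )
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        return df

    def entries_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=[s.value for s in LOGICAL_STATES])
        df.insert(0, "cycle", np.arange(self.n_cycles))
        return df


def state_space_for(
    params: TransitionParameters, config: ModelConfig
) -> StateSpace:
    return StateSpace(
        max_tunnel_years=params.max_tunnel_years,
        cycles_per_tunnel_year=cycles_per_tunnel_year(
            config.cycle_length_days, config.days_per_year
        ),
    )


def run_cohort(
    bundle: ParameterBundle,
    arm_name: str,
    n_cycles: int | None = None,
) -> CohortTrace:
    """Iterate the cohort forward and record occupancy and entry flows."""
    bundle.validate()
    config = bundle.config
    params = bundle.transitions
    arm = bundle.arms[arm_name]
    space = state_space_for(params, config)
    if n_cycles is None:
        n_cycles = config.n_cycles

    agg = space.aggregation_matrix()
    logical_idx = agg.argmax(axis=1)
    # same_logical[i, j] == True when i and j collapse to one logical state
    same_logical = logical_idx[:, None] == logical_idx[None, :]

    n = space.n_states
    occupancy = np.zeros((n_cycles + 1, n))
    entries = np.zeros((n_cycles, len(LOGICAL_STATES)))
    occupancy[0, space.i_active_1l] = 1.0

    age_dependent = config.background_mortality == "lifetable"
    T = build_transition_matrix(
        params, arm, config, space, cycle_index=0, life_table=bundle.life_table
    )
    for t in range(n_cycles):
        if age_dependent and t > 0:
            T = build_transition_matrix(
                params, arm, config, space, cycle_index=t, life_table=bundle.life_table
            )
        occ = occupancy[t]
        flow = occ[:, None] * T
        cross = np.where(same_logical, 0.0, flow)  # flows between logical states
        entries[t] = cross.sum(axis=0) @ agg
        occupancy[t + 1] = occ @ T
        if not np.all(np.isfinite(occupancy[t + 1])):
            raise NumericError(f"non-finite occupancy at cycle {t + 1}")

    trace = CohortTrace(
        arm=arm_name, occupancy=occupancy, entries=entries, space=space, config=config
    )
    trace.check_conservation(tol=1e-9 if age_dependent else CONSERVATION_TOL)
    return trace
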