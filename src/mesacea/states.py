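"""Health states of the ulcerative-colitis treatment pathway.

The model distinguishes eight logical health states: three active
mesalazine-treated states (first line at 2,400 mg/day, first line at the
increased 4,800 mg/day dose, second line with an added oral corticosteroid),
hospitalisation without surgery after mesalazine failure, surgery,
post-surgery, remission and death.

Remission is expanded into *tunnel* sub-states so that the relapse
probability can depend on the number of completed years spent in remission
while the process stays Markovian.  The tunnel is cycle-granular: one
sub-state per 8-week cycle within each tunnel year, plus a single terminal
sub-state once the maximum tracked tunnel year is reached.  Aggregating the
tunnel sub-states recovers the single logical remission state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class HealthState(str, Enum):
    """The eight logical health states."""

    ACTIVE_1L = "ACTIVE_1L"
    ACTIVE_1L_HIGH = "ACTIVE_1L_HIGH"
    ACTIVE_2L = "ACTIVE_2L"
    FAILURE_RELAPSE = "FAILURE_RELAPSE"
    SURGERY = "SURGERY"
    POST_SURGERY = "POST_SURGERY"
    REMISSION = "REMISSION"
    DEATH = "DEATH"


#: Logical states in canonical order.
LOGICAL_STATES: tuple[HealthState, ...] = tuple(HealthState)

#: States in which patients are alive.
ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEATH)

#: Active-disease states treated with mesalazine.
ACTIVE_STATES = (
    HealthState.ACTIVE_1L,
    HealthState.ACTIVE_1L_HIGH,
    HealthState.ACTIVE_2L,
)


@dataclass(frozen=True)
class StateSpace:
    """Expanded state list with remission tunnel sub-states.

    Parameters
    ----------
    max_tunnel_years
        Number of tunnel years after which the relapse probability stops
        decreasing (the terminal tunnel sub-state).
    cycles_per_tunnel_year
        Model cycles per tunnel year; with 8-week cycles and a 365.25-day
        year this is ``ceil(365.25 / 56) = 7``.
    """

    max_tunnel_years: int = 5
    cycles_per_tunnel_year: int = 7
    labels: tuple[str, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.max_tunnel_years < 1:
            raise ValueError("max_tunnel_years must be >= 1")
        if self.cycles_per_tunnel_year < 1:
            raise ValueError("cycles_per_tunnel_year must be >= 1")
        labels = [
            HealthState.ACTIVE_1L.value,
            HealthState.ACTIVE_1L_HIGH.value,
            HealthState.ACTIVE_2L.value,
            HealthState.FAILURE_RELAPSE.value,
            HealthState.SURGERY.value,
            HealthState.POST_SURGERY.value,
        ]
        for year in range(self.max_tunnel_years):
            for c in range(self.cycles_per_tunnel_year):
                labels.append(f"REMISSION_Y{year}C{c}")
        labels.append(f"REMISSION_Y{self.max_tunnel_years}")
        labels.append(HealthState.DEATH.value)
        object.__setattr__(self, "labels", tuple(labels))

    # -- indices -----------------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def n_remission(self) -> int:
        return self.max_tunnel_years * self.cycles_per_tunnel_year + 1

    @property
    def i_active_1l(self) -> int:
        return 0

    @property
    def i_active_1l_high(self) -> int:
        return 1

    @property
    def i_active_2l(self) -> int:
        return 2

    @property
    def i_failure(self) -> int:
        return 3

    @property
    def i_surgery(self) -> int:
        return 4

    @property
    def i_post_surgery(self) -> int:
        return 5

    @property
    def i_remission_start(self) -> int:
        """Index of the first remission tunnel sub-state (year 0, cycle 0)."""
        return 6

    @property
    def i_death(self) -> int:
        return self.n_states - 1

    @property
    def remission_slice(self) -> slice:
        return slice(self.i_remission_start, self.i_death)

    # -- tunnel bookkeeping ------------------------------------------------

    def tunnel_year(self, index: int) -> int:
        """Completed tunnel years for remission sub-state ``index``."""
        k = index - self.i_remission_start
        if not 0 <= k < self.n_remission:
            raise IndexError(f"state {index} is not a remission sub-state")
        return min(k // self.cycles_per_tunnel_year, self.max_tunnel_years)

    def next_remission_index(self, index: int) -> int:
        """Sub-state reached after one further cycle spent in remission."""
        k = index - self.i_remission_start
        if not 0 <= k < self.n_remission:
            raise IndexError(f"state {index} is not a remission sub-state")
        return index if k == self.n_remission - 1 else index + 1

    # -- logical aggregation ----------------------------------------------

    def logical_of(self, index: int) -> HealthState:
        if self.i_remission_start <= index < self.i_death:
            return HealthState.REMISSION
        return HealthState(self.labels[index])

    def aggregation_matrix(self) -> np.ndarray:
        """0/1 matrix mapping expanded states (rows) to logical states (cols)."""
        agg = np.zeros((self.n_states, len(LOGICAL_STATES)))
        for i in range(self.n_states):
            agg[i, LOGICAL_STATES.index(self.logical_of(i))] = 1.0
        return agg

    def aggregate(self, occupancy: np.ndarray) -> np.ndarray:
        """Collapse an (..., n_states) occupancy array to the 8 logical states."""
        return np.asarray(occupancy) @ self.aggregation_matrix()


def cycles_per_tunnel_year(cycle_length_days: float, days_per_year: float) -> int:
    """Cycles per tunnel year: nearest-integer-above yearly granularity."""
    return math.ceil(days_per_year / cycle_length_days)
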