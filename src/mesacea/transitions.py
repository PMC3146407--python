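"""Transition-matrix assembly for the UC treatment pathway.

The matrix is row-stochastic over the expanded state list (tunnel
sub-states included).  With background mortality off it is
cycle-invariant; time-in-remission dependence is carried entirely by the
tunnel sub-states, and age dependence enters only through the optional
life-table adjustment.
"""

from __future__ import annotations

import numpy as np

from .parameters import (
    LifeTable,
    ModelConfig,
    ParameterError,
    TransitionParameters,
    TreatmentArm,
)
from .states import StateSpace

ROW_SUM_TOL = 1e-9


class MatrixAssemblyError(RuntimeError):
    """An assembled transition-matrix row does not sum to one."""


def annual_to_cycle_probability(p_annual: float, cycle_years: float) -> float:
    """Convert an annual probability to an equivalent per-cycle probability.

    Assumes a constant hazard within the year, giving
    ``1 - (1 - p_annual) ** cycle_years``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ParameterError(f"p_annual must be in [0, 1], got {p_annual!r}")
    if cycle_years <= 0:
        raise ParameterError("cycle_years must be positive")
    return 1.0 - (1.0 - p_annual) ** cycle_years


def relapse_probability(
    params: TransitionParameters,
    arm: TreatmentArm | str,
    tunnel_year: int,
    cycle_years: float = 56.0 / 365.25,
) -> float:
    """Per-cycle remission→relapse probability after ``tunnel_year`` years.

    The year-0 value comes from the arm's relapse parameter on its declared
    time basis; each further completed year in remission lowers it by the
    relative decrement (1 %/year by default), floored at zero.
    """
    if tunnel_year < 0:
        raise ParameterError("tunnel_year must be non-negative")
    name = arm if isinstance(arm, str) else arm.name
    base = params.p_relapse[name]
    if params.relapse_basis == "annual":
        p0 = annual_to_cycle_probability(base, cycle_years)
    else:
        p0 = base
    year = min(tunnel_year, params.max_tunnel_years)
    return max(p0 * (1.0 - params.langholz_decrement_per_year * year), 0.0)


def build_transition_matrix(
    params: TransitionParameters,
    arm: TreatmentArm,
    config: ModelConfig,
    space: StateSpace,
    cycle_index: int = 0,
    life_table: LifeTable | None = None,
) -> np.ndarray:
    """Assemble the row-stochastic transition matrix for one arm.

    With ``config.background_mortality == "lifetable"`` the age-specific
    per-cycle death probability at the cohort's current age is layered on
    top of every alive state's row.
    """
    if cycle_index < 0:
        raise ParameterError("cycle_index must be non-negative")
    name = arm.name
    n = space.n_states
    T = np.zeros((n, n))

    p1 = params.p_remit_1l[name]
    p1h = params.p_remit_1l_high[name]
    rem0 = space.i_remission_start

    T[space.i_active_1l, rem0] = p1
    T[space.i_active_1l, space.i_active_1l_high] = 1.0 - p1
    T[space.i_active_1l_high, rem0] = p1h
    T[space.i_active_1l_high, space.i_active_2l] = 1.0 - p1h
    T[space.i_active_2l, rem0] = params.p_remit_2l
    T[space.i_active_2l, space.i_failure] = 1.0 - params.p_remit_2l
    T[space.i_failure, rem0] = params.p_remit_hosp
    T[space.i_failure, space.i_surgery] = params.p_surgery_hosp
    T[space.i_surgery, space.i_post_surgery] = 1.0 - params.p_death_surgery
    T[space.i_surgery, space.i_death] = params.p_death_surgery
    T[space.i_post_surgery, space.i_post_surgery] = 1.0
    T[space.i_death, space.i_death] = 1.0

    for i in range(rem0, space.i_death):
        p_rel = relapse_probability(
            params, arm, space.tunnel_year(i), config.cycle_years
        )
        T[i, space.i_active_1l] = p_rel
        T[i, space.next_remission_index(i)] += 1.0 - p_rel

    if config.background_mortality == "lifetable":
        if life_table is None:
            raise ParameterError("life table required for background mortality")
        T = apply_background_mortality(
            T,
            life_table,
            config.age_at_cycle(cycle_index),
            config.cycle_years,
            death_index=space.i_death,
        )

    _check_rows(T)
    return T


def apply_background_mortality(
    matrix: np.ndarray,
    life_table: LifeTable,
    age: float,
    cycle_years: float,
    death_index: int = -1,
) -> np.ndarray:
    """Layer age-specific all-cause mortality onto a transition matrix.

    For every alive state the per-cycle death probability ``q`` (annual
    probability at the cohort's current integer age, converted to the cycle
    length) is added to the death column and all other entries are rescaled
    by ``1 - q``.  The death row is untouched.
    """
    T = np.array(matrix, dtype=float)
    n = T.shape[0]
    death_index = range(n)[death_index]
    q = annual_to_cycle_probability(life_table.annual_probability(age), cycle_years)
    for i in range(n):
        if i == death_index:
            continue
        T[i, :] *= 1.0 - q
        T[i, death_index] += q
    _check_rows(T)
    return T


def _check_rows(T: np.ndarray) -> None:
    sums = T.sum(axis=1)
    bad = np.abs(sums - 1.0) > ROW_SUM_TOL
    if np.any(bad):
        i = int(np.argmax(bad))
        raise MatrixAssemblyError(
            f"row {i} sums to {sums[i]!r}, deviates from 1 by more than {ROW_SUM_TOL}"
        )
    if np.any(T < -ROW_SUM_TOL) or np.any(T > 1 + ROW_SUM_TOL):
        raise MatrixAssemblyError("transition probabilities outside [0, 1]")
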