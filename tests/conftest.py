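import numpy as np
import pytest

from mesacea import MarkovCEModel, make_base_case
from mesacea.parameters import ParameterBundle


@pytest.fixture
def base_bundle() -> ParameterBundle:
    """Fresh base-case bundle (mutable per test)."""
    return make_base_case()


@pytest.fixture(scope="session")
def base_results():
    """Deterministic base-case results, evaluated once per session."""
    return MarkovCEModel.base_case().fit()


@pytest.fixture
def table1_bundle() -> ParameterBundle:
    """Literal transition-table reading: verbatim per-cycle relapse values
    and the UK-audit hospitalisation→surgery share."""
    bundle = make_base_case()
    bundle.transitions.relapse_basis = "per_cycle"
    bundle.transitions.p_surgery_hosp = 0.258
    bundle.transitions.p_remit_hosp = 0.742
    return bundle


def microsimulate(bundle, arm_name, n_patients, seed):
    """Independent per-individual microsimulation with the same matrices.

    Returns an occupancy array shaped like the cohort trace, for use as a
    Monte-Carlo oracle against the deterministic cohort iteration.
    """
    from mesacea.cohort import state_space_for
    from mesacea.transitions import build_transition_matrix

    space = state_space_for(bundle.transitions, bundle.config)
    T = build_transition_matrix(
        bundle.transitions,
        bundle.arms[arm_name],
        bundle.config,
        space,
        life_table=bundle.life_table,
    )
    cum = np.cumsum(T, axis=1)
    rng = np.random.default_rng(seed)
    states = np.full(n_patients, space.i_active_1l, dtype=np.int64)
    n_cycles = bundle.config.n_cycles
    occupancy = np.zeros((n_cycles + 1, space.n_states))
    occupancy[0] = np.bincount(states, minlength=space.n_states) / n_patients
    for t in range(n_cycles):
        r = rng.random(n_patients)
        states = (cum[states] < r[:, None]).sum(axis=1)
        occupancy[t + 1] = np.bincount(states, minlength=space.n_states) / n_patients
    return occupancy
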