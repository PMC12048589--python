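import pytest

from racas import AgentSpec, run_session
from racas.schedule import (
    ScheduleState,
    advance_state,
    allocate_trial,
)


def drive_scheduler(choices):
    """Drive the scheduler with an explicit choice sequence (no agent).

    Returns (allocations, obtained_flags, states) where states[i] is the
    state *before* trial i+1.
    """
    state = ScheduleState()
    allocations, obtained_flags, states = [], [], [state]
    for choice in choices:
        alloc = allocate_trial(state)
        obtained = (choice == "P" and alloc.alloc_plus) or (
            choice == "M" and alloc.alloc_minus
        )
        state = advance_state(state, alloc, choice)
        allocations.append(alloc)
        obtained_flags.append(obtained)
        states.append(state)
    return allocations, obtained_flags, states


@pytest.fixture(scope="session")
def always_plus_session():
    return run_session(AgentSpec("always_plus"), seed=0)


@pytest.fixture(scope="session")
def always_minus_session():
    return run_session(AgentSpec("always_minus"), seed=0)


@pytest.fixture(scope="session")
def all_kind_specs():
    """One representative spec per agent kind."""
    return [
        AgentSpec("always_plus"),
        AgentSpec("always_minus"),
        AgentSpec("bernoulli", {"p_plus": 0.5}),
        AgentSpec("wsls", {"stay_after_reward": 0.9, "shift_after_no_reward": 0.8}),
        AgentSpec("qlearn", {"alpha": 0.2, "epsilon": 0.1}),
        AgentSpec("regularity_seeker", {"commitment_gain": 0.15, "exploration_floor": 0.1}),
    ]


@pytest.fixture(scope="session")
def mixed_batch(all_kind_specs):
    """A modest batch of sessions covering every agent kind."""
    from racas import run_experiment

    return run_experiment(all_kind_specs, n_per_spec=20, base_seed=123)
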