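"""Run agents against the RaCaS scheduler and batch experiments.

The per-trial event order is fixed: the scheduler commits the trial's
allocation, the agent chooses a side, the obtained reward is revealed
(feedback only on the chosen option), the agent updates, and the scheduler
state advances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import schedule as sched
from .agents import Agent, AgentSpec, agent_init
from .errors import ValidationError
from .schedule import BUDGET_PER_SIDE, MINUS, N_TRIALS, PLUS, Allocation, ScheduleState

__all__ = ["TrialRecord", "SessionResult", "run_session", "run_experiment", "derive_seed"]


@dataclass(slots=True)
class TrialRecord:
    """One trial: the choice, the (pre-committed) allocation, the outcome."""

    trial: int
    choice: str
    alloc_plus: bool
    alloc_minus: bool
    obtained: bool


@dataclass(slots=True)
class SessionResult:
    """A complete 100-trial session plus its provenance.

    ``agent`` is a plain label (stable across file round-trips);
    ``agent_spec`` carries the full spec when the session was simulated
    in-process and is ``None`` for sessions loaded from files.
    """

    records: list[TrialRecord]
    agent: str
    seed: int
    session_id: str = ""
    agent_spec: AgentSpec | None = None

    def validate(self) -> None:
        """Assert every structural invariant of a complete session."""
        if len(self.records) != N_TRIALS:
            raise ValidationError(
                f"session {self.session_id!r}: expected {N_TRIALS} records, "
                f"got {len(self.records)}"
            )
        if [r.trial for r in self.records] != list(range(1, N_TRIALS + 1)):
            raise ValidationError(f"session {self.session_id!r}: trial indices not 1..100")
        total_plus = sum(r.alloc_plus for r in self.records)
        total_minus = sum(r.alloc_minus for r in self.records)
        if total_plus != BUDGET_PER_SIDE or total_minus != BUDGET_PER_SIDE:
            raise ValidationError(
                f"session {self.session_id!r}: allocated {total_plus} Bias+ / "
                f"{total_minus} Bias- rewards; expected {BUDGET_PER_SIDE} each"
            )
        for r in self.records:
            expected = (r.choice == PLUS and r.alloc_plus) or (
                r.choice == MINUS and r.alloc_minus
            )
            if r.obtained != expected:
                raise ValidationError(
                    f"session {self.session_id!r}, trial {r.trial}: obtained flag "
                    "inconsistent with choice and allocation"
                )

    @property
    def choices(self) -> list[str]:
        return [r.choice for r in self.records]

    def total_obtained(self) -> int:
        return sum(r.obtained for r in self.records)


def run_session(
    spec: AgentSpec,
    seed: int | None = None,
    *,
    session_id: str = "",
    commitment_threshold: int = sched.DEFAULT_COMMITMENT_THRESHOLD,
    recommit_threshold: int = sched.DEFAULT_RECOMMIT_THRESHOLD,
) -> SessionResult:
    """Play one 100-trial session of the agent against the scheduler.

    ``seed`` overrides ``spec.seed`` when given, so a single spec can be
    replicated across seeds.  Deterministic in ``(spec, seed)``.
    """
    if seed is not None:
        spec = AgentSpec(kind=spec.kind, params=spec.params, seed=seed)
    agent: Agent = agent_init(spec)

    state = ScheduleState()
    records: list[TrialRecord] = []
    for t in range(1, N_TRIALS + 1):
        alloc: Allocation = sched.allocate_trial(state, commitment_threshold)
        choice = agent.choose()
        obtained = (choice == PLUS and alloc.alloc_plus) or (
            choice == MINUS and alloc.alloc_minus
        )
        agent.update(choice, obtained)
        state = sched.advance_state(state, alloc, choice, recommit_threshold)
        records.append(
            TrialRecord(
                trial=t,
                choice=choice,
                alloc_plus=alloc.alloc_plus,
                alloc_minus=alloc.alloc_minus,
                obtained=obtained,
            )
        )

    result = SessionResult(
        records=records,
        agent=spec.label(),
        seed=spec.seed,
        session_id=session_id or f"{spec.label()}_s{spec.seed}",
        agent_spec=spec,
    )
    result.validate()  # internal-consistency hook: must never fire
    return result


def derive_seed(base_seed: int, spec_index: int, replicate: int) -> int:
    """Derive a per-session seed from (base seed, spec index, replicate).

    Uses a splittable ``SeedSequence`` so batches are reproducible and can
    be extended with more specs or replicates without disturbing existing
    sessions.  The result fits in a signed 32-bit integer.
    """
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(spec_index, replicate))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_experiment(
    specs: list[AgentSpec],
    n_per_spec: int,
    base_seed: int = 0,
    **scheduler_kwargs,
) -> list[SessionResult]:
    """Run ``n_per_spec`` sessions for each agent spec, with derived seeds.

    Sessions are ordered by spec then replicate and labelled
    ``"<agent label>_r<replicate>"``.
    """
    if not specs:
        raise ValidationError("run_experiment requires at least one agent spec")
    if n_per_spec < 1:
        raise ValidationError(f"n_per_spec must be >= 1, got {n_per_spec}")
    results = []
    for i, spec in enumerate(specs):
        for rep in range(n_per_spec):
            seed = derive_seed(base_seed, i, rep)
            results.append(
                run_session(
                    spec,
                    seed,
                    session_id=f"{spec.label()}_r{rep}",
                    **scheduler_kwargs,
                )
            )
    return results
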