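"""The RaCaS reward scheduler as a pure, deterministic state machine.

RaCaS ("Regularity as Carrot and Stick") allocates a fixed budget of 25
rewards to each of two options -- the target option Bias+ and the non-target
option Bias- -- over a 100-trial two-alternative forced-choice session.
Rewards on Bias+ follow a trackable pattern: after ``X`` non-rewarded clicks
on Bias+, the next Bias+ click is rewarded, where ``X`` steps through
1, 2, 3, 4, 3, 2 across six pre-defined stages of the session (the carrot).
Choosing Bias- suspends the pattern until the agent recommits to Bias+
(the stick).  Bias- rewards are hidden: they are co-allocated with Bias+
rewards only while the agent is highly committed to Bias+, and any residue
is dumped into the final trials, where a per-side forcing rule guarantees
that exactly 25 rewards per side are allocated in every complete session.

The scheduler is deterministic: the allocation for a trial is a pure
function of the choice/reward history, computed *before* the choice on that
trial and therefore never a function of it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from .errors import SessionCompleteError, ValidationError

#: Side labels used throughout the package (and in session CSV files).
PLUS = "P"
MINUS = "M"
SIDES = (PLUS, MINUS)

#: Number of trials in a session and per-side reward budget.
N_TRIALS = 100
BUDGET_PER_SIDE = 25

#: Six-stage schedule: (stage_id, first trial, last trial, interval X).
#: X is the number of non-rewarded Bias+ clicks required before the next
#: Bias+ click carries a reward.
STAGE_TABLE: tuple[tuple[int, int, int, int], ...] = (
    (0, 1, 11, 1),
    (1, 12, 25, 2),
    (2, 26, 40, 3),
    (3, 41, 60, 4),
    (4, 61, 80, 3),
    (5, 81, 100, 2),
)

#: Default commitment threshold C: consecutive Bias+ choices required before
#: a Bias- reward may ride along with a Bias+ reward (co-allocation).
DEFAULT_COMMITMENT_THRESHOLD = 5

#: Default recommitment threshold R: consecutive Bias+ choices required after
#: a defection to Bias- before the reward pattern restarts.
DEFAULT_RECOMMIT_THRESHOLD = 2


def stage_for_trial(trial: int) -> tuple[int, int]:
    """Return ``(stage_id, X)`` for a 1-based trial index.

    Parameters
    ----------
    trial
        Trial index in ``1..100``.

    Raises
    ------
    ValidationError
        If ``trial`` lies outside the session.
    """
    if not 1 <= trial <= N_TRIALS:
        raise ValidationError(f"trial index must be in 1..{N_TRIALS}, got {trial}")
    for stage_id, lo, hi, x in STAGE_TABLE:
        if lo <= trial <= hi:
            return stage_id, x
    raise AssertionError("unreachable: stage table partitions 1..100")


@dataclass(slots=True)
class Allocation:
    """Per-trial reward placement, fixed before the agent's choice.

    Both flags may be true on the same trial: co-allocation is how Bias-
    rewards are hidden behind Bias+ rewards, and the endgame forcing rule
    can fire for both sides at once.
    """

    alloc_plus: bool
    alloc_minus: bool


@dataclass(slots=True)
class ScheduleState:
    """Complete memory of the scheduler between trials.

    Attributes
    ----------
    trial_index
        1-based index of the *next* trial to be played; 101 marks a
        complete session.
    plus_cycle_count
        Bias+ clicks accumulated in the current reward cycle.  Reaching the
        effective interval X arms a Bias+ reward for the next trial.
    unrewarded_streak
        Consecutive clicks (either side) without an obtained reward; hitting
        10 triggers the simplified schedule (``reset_mode``).
    consecutive_plus
        Consecutive Bias+ choices ending at the last trial.
    plus_budget, minus_budget
        Rewards not yet allocated on each side (start at 25).
    reset_mode
        Simplified schedule active (effective X = 1) until the next
        obtained reward.
    awaiting_recommit
        Pattern suspended after a defection to Bias-, pending recommitment.
    """

    trial_index: int = 1
    plus_cycle_count: int = 0
    unrewarded_streak: int = 0
    consecutive_plus: int = 0
    plus_budget: int = BUDGET_PER_SIDE
    minus_budget: int = BUDGET_PER_SIDE
    reset_mode: bool = False
    awaiting_recommit: bool = False

    def as_dict(self) -> dict:
        """Plain key-value view for logging and debugging."""
        return asdict(self)


def allocate_trial(
    state: ScheduleState,
    commitment_threshold: int = DEFAULT_COMMITMENT_THRESHOLD,
) -> Allocation:
    """Decide reward placement for the upcoming trial.

    A pure function of ``state`` (hence of the full history); the agent's
    imminent choice cannot influence it.

    The Bias+ reward fires either by the pattern rule -- the cycle counter
    has reached the effective interval (X = 1 while ``reset_mode``), the
    pattern is not suspended, and budget remains -- or by the forcing rule,
    when the remaining trials can only just accommodate the remaining
    budget.  The Bias- reward fires either by co-allocation (a Bias+ reward
    fires and the agent has made at least ``commitment_threshold``
    consecutive Bias+ choices) or by the same forcing rule on its own
    budget.  An empty budget never allocates.

    Raises
    ------
    SessionCompleteError
        If the session has already run its 100 trials.
    """
    t = state.trial_index
    if t > N_TRIALS:
        raise SessionCompleteError("session complete: all 100 trials played")
    remaining = N_TRIALS - t + 1

    effective_x = 1 if state.reset_mode else stage_for_trial(t)[1]
    pattern_ready = (
        state.plus_cycle_count >= effective_x
        and not state.awaiting_recommit
        and state.plus_budget > 0
    )
    force_plus = 0 < state.plus_budget >= remaining
    alloc_plus = pattern_ready or force_plus

    co_allocate = (
        alloc_plus
        and state.consecutive_plus >= commitment_threshold
        and state.minus_budget > 0
    )
    force_minus = 0 < state.minus_budget >= remaining
    alloc_minus = co_allocate or force_minus

    return Allocation(alloc_plus=alloc_plus, alloc_minus=alloc_minus)


def advance_state(
    state: ScheduleState,
    alloc: Allocation,
    choice: str,
    recommit_threshold: int = DEFAULT_RECOMMIT_THRESHOLD,
) -> ScheduleState:
    """Fold one completed trial into a new scheduler state.

    Budgets are spent on allocation, whether or not the reward was obtained
    (a reward placed on the unchosen side is simply missed).  The reward is
    obtained iff the chosen side carried one.  Bookkeeping:

    * ``unrewarded_streak`` resets on an obtained reward, else increments;
      reaching 10 switches on ``reset_mode`` and zeroes the streak.
    * a Bias+ choice extends ``consecutive_plus`` and, unless the pattern is
      suspended, advances the reward cycle (the cycle restarts after a
      rewarded click); a Bias- choice zeroes both counters and suspends the
      pattern.
    * the suspension clears once ``consecutive_plus`` reaches
      ``recommit_threshold``, with the cycle restarting from zero.
    * ``reset_mode`` clears on the first obtained reward.
    """
    if choice not in SIDES:
        raise ValidationError(f"choice must be one of {SIDES}, got {choice!r}")
    if state.trial_index > N_TRIALS:
        raise SessionCompleteError("session complete: all 100 trials played")

    obtained = (choice == PLUS and alloc.alloc_plus) or (
        choice == MINUS and alloc.alloc_minus
    )

    plus_budget = state.plus_budget - (1 if alloc.alloc_plus else 0)
    minus_budget = state.minus_budget - (1 if alloc.alloc_minus else 0)
    if plus_budget < 0 or minus_budget < 0:
        raise ValidationError("allocation from an empty budget")

    reset_mode = state.reset_mode
    if obtained:
        unrewarded_streak = 0
        reset_mode = False
    else:
        unrewarded_streak = state.unrewarded_streak + 1
        if unrewarded_streak >= 10:
            reset_mode = True
            unrewarded_streak = 0

    plus_cycle = state.plus_cycle_count
    consecutive_plus = state.consecutive_plus
    awaiting = state.awaiting_recommit
    if choice == PLUS:
        consecutive_plus += 1
        if awaiting:
            if consecutive_plus >= recommit_threshold:
                awaiting = False
                plus_cycle = 0
        else:
            plus_cycle = 0 if obtained else plus_cycle + 1
    else:
        consecutive_plus = 0
        plus_cycle = 0
        awaiting = True

    return ScheduleState(
        trial_index=state.trial_index + 1,
        plus_cycle_count=plus_cycle,
        unrewarded_streak=unrewarded_streak,
        consecutive_plus=consecutive_plus,
        plus_budget=plus_budget,
        minus_budget=minus_budget,
        reset_mode=reset_mode,
        awaiting_recommit=awaiting,
    )


def always_plus_reward_trials(
    commitment_threshold: int = DEFAULT_COMMITMENT_THRESHOLD,
    recommit_threshold: int = DEFAULT_RECOMMIT_THRESHOLD,
) -> list[int]:
    """Trial indices at which a fully committed (always-Bias+) agent is rewarded.

    Test/oracle helper: runs the state machine against the constant Bias+
    policy and reports the trials whose allocated Bias+ reward was collected.
    """
    state = ScheduleState()
    rewarded: list[int] = []
    for t in range(1, N_TRIALS + 1):
        alloc = allocate_trial(state, commitment_threshold)
        if alloc.alloc_plus:
            rewarded.append(t)
        state = advance_state(state, alloc, PLUS, recommit_threshold)
    return rewarded
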