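"""Simulated decision-makers for the two-alternative task.

Each agent chooses a side every trial and updates on the reward it obtained
(agents never see the unchosen side's allocation -- feedback is only given
for the chosen option, as in the task).  Agents stand in for the human
participants: deterministic policies probe the scheduler's edge cases,
reward-learning agents (Q-learning, win-stay/lose-shift) probe how far plain
reward learning is pulled by the schedule, and the regularity seeker is a
demonstration heuristic that actively tracks the reward pattern.

Every stochastic agent draws from a private ``numpy`` Generator seeded from
its spec, so identical ``(spec, seed)`` pairs reproduce identical choice
sequences against a fixed schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError
from .schedule import MINUS, PLUS

AGENT_KINDS = (
    "always_plus",
    "always_minus",
    "bernoulli",
    "wsls",
    "qlearn",
    "regularity_seeker",
)


@dataclass(frozen=True)
class AgentSpec:
    """Declarative description of an agent: kind, parameters, seed."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in AGENT_KINDS:
            raise ValidationError(
                f"unknown agent kind {self.kind!r}; expected one of {AGENT_KINDS}"
            )
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValidationError(f"seed must be a non-negative integer, got {self.seed!r}")
        _validate_params(self.kind, self.params)

    def label(self) -> str:
        """Stable human-readable label used in session tables."""
        if not self.params:
            return self.kind
        inner = ",".join(f"{k}={self.params[k]}" for k in sorted(self.params))
        return f"{self.kind}({inner})"


def _check_prob(params: dict, name: str, lo_open: bool = False) -> None:
    v = params.get(name)
    if v is None:
        return
    ok = (lo_open and 0 < v <= 1) or (not lo_open and 0 <= v <= 1)
    if not ok:
        interval = "(0, 1]" if lo_open else "[0, 1]"
        raise ValidationError(f"parameter {name}={v!r} outside {interval}")


def _validate_params(kind: str, params: dict) -> None:
    allowed = {
        "always_plus": set(),
        "always_minus": set(),
        "bernoulli": {"p_plus"},
        "wsls": {"stay_after_reward", "shift_after_no_reward"},
        "qlearn": {"alpha", "epsilon", "q0_plus", "q0_minus"},
        "regularity_seeker": {"commitment_gain", "exploration_floor"},
    }[kind]
    unknown = set(params) - allowed
    if unknown:
        raise ValidationError(f"unknown parameters for {kind}: {sorted(unknown)}")
    if kind == "bernoulli":
        _check_prob(params, "p_plus")
    elif kind == "wsls":
        _check_prob(params, "stay_after_reward")
        _check_prob(params, "shift_after_no_reward")
    elif kind == "qlearn":
        _check_prob(params, "alpha", lo_open=True)
        _check_prob(params, "epsilon")
    elif kind == "regularity_seeker":
        _check_prob(params, "commitment_gain")
        _check_prob(params, "exploration_floor")


class Agent:
    """Base agent: a choice policy plus an update rule.

    Subclasses implement :meth:`choose` and may override :meth:`update`.
    ``self.rng`` is the agent's private random stream.
    """

    def __init__(self, spec: AgentSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)

    def choose(self) -> str:
        raise NotImplementedError

    def update(self, choice: str, obtained: bool) -> None:  # noqa: B027
        """Fold the trial's outcome into the agent's memory (default: none)."""


class AlwaysPlus(Agent):
    def choose(self) -> str:
        return PLUS


class AlwaysMinus(Agent):
    def choose(self) -> str:
        return MINUS


class Bernoulli(Agent):
    """Memoryless agent choosing Bias+ with fixed probability ``p_plus``."""

    def __init__(self, spec: AgentSpec):
        super().__init__(spec)
        self.p_plus = float(spec.params.get("p_plus", 0.5))

    def choose(self) -> str:
        return PLUS if self.rng.random() < self.p_plus else MINUS


class WinStayLoseShift(Agent):
    """Probabilistic win-stay/lose-shift.

    After a reward, repeat the last choice with probability
    ``stay_after_reward``; after no reward, switch with probability
    ``shift_after_no_reward``.  The first trial is a fair coin flip.
    """

    def __init__(self, spec: AgentSpec):
        super().__init__(spec)
        self.stay_after_reward = float(spec.params.get("stay_after_reward", 1.0))
        self.shift_after_no_reward = float(spec.params.get("shift_after_no_reward", 1.0))
        self.last_choice: str | None = None
        self.last_obtained = False

    def choose(self) -> str:
        if self.last_choice is None:
            return PLUS if self.rng.random() < 0.5 else MINUS
        if self.last_obtained:
            stay = self.rng.random() < self.stay_after_reward
        else:
            stay = not (self.rng.random() < self.shift_after_no_reward)
        if stay:
            return self.last_choice
        return MINUS if self.last_choice == PLUS else PLUS

    def update(self, choice: str, obtained: bool) -> None:
        self.last_choice = choice
        self.last_obtained = obtained


class QLearner(Agent):
    """Tabular delta-rule learner with epsilon-greedy choice.

    The chosen side's value moves toward the obtained reward,
    ``V <- V + alpha * (r - V)``; the unchosen side is untouched.  With
    probability ``epsilon`` the agent explores uniformly; ties between equal
    values are broken by a fair coin.
    """

    def __init__(self, spec: AgentSpec):
        super().__init__(spec)
        p = spec.params
        self.alpha = float(p.get("alpha", 0.1))
        self.epsilon = float(p.get("epsilon", 0.1))
        self.values = {PLUS: float(p.get("q0_plus", 0.5)), MINUS: float(p.get("q0_minus", 0.5))}

    def choose(self) -> str:
        if self.epsilon > 0 and self.rng.random() < self.epsilon:
            return PLUS if self.rng.random() < 0.5 else MINUS
        vp, vm = self.values[PLUS], self.values[MINUS]
        if vp == vm:
            return PLUS if self.rng.random() < 0.5 else MINUS
        return PLUS if vp > vm else MINUS

    def update(self, choice: str, obtained: bool) -> None:
        r = 1.0 if obtained else 0.0
        self.values[choice] += self.alpha * (r - self.values[choice])


class RegularitySeeker(Agent):
    """Heuristic agent attracted to a trackable reward pattern on Bias+.

    A demonstration device, not a model fitted to human data.  The agent
    tracks the interval (in Bias+ clicks) between consecutive rewards on
    Bias+.  While rewards keep arriving at the last interval give or take
    one click -- i.e. the pattern looks like a slowly drifting arithmetic
    sequence -- each reward counts as a confirmed prediction and commitment
    to Bias+ rises by ``commitment_gain``.  A wait that overshoots the
    expected interval counts as one violation: commitment falls by the same
    amount and the pattern hypothesis is abandoned until the next reward
    re-anchors it (without penalty -- the overdue wait, not the reward, is
    the punishment).  The probability of choosing Bias+ equals the current
    commitment, clipped to ``[exploration_floor, 1 - exploration_floor]``.
    """

    def __init__(self, spec: AgentSpec):
        super().__init__(spec)
        self.gain = float(spec.params.get("commitment_gain", 0.15))
        self.floor = float(spec.params.get("exploration_floor", 0.05))
        self.commitment = self._clip(0.6)  # mild initial pull toward the target
        self.clicks_since_reward = 0  # Bias+ clicks since last Bias+ reward
        self.last_interval: int | None = None

    def _clip(self, value: float) -> float:
        return float(np.clip(value, self.floor, 1.0 - self.floor))

    def _bump(self, confirmed: bool) -> None:
        delta = self.gain if confirmed else -self.gain
        self.commitment = self._clip(self.commitment + delta)

    def choose(self) -> str:
        return PLUS if self.rng.random() < self.commitment else MINUS

    def update(self, choice: str, obtained: bool) -> None:
        if choice != PLUS:
            return
        self.clicks_since_reward += 1
        if obtained:
            interval = self.clicks_since_reward
            if self.last_interval is None or abs(interval - self.last_interval) <= 1:
                # fresh anchor or confirmed prediction: regularity reinforces
                self._bump(confirmed=True)
            # an off-prediction reward re-anchors the hypothesis, no penalty:
            # the punishment is the overdue wait itself, not the reward
            self.last_interval = interval
            self.clicks_since_reward = 0
        elif (
            self.last_interval is not None
            and self.clicks_since_reward > self.last_interval + 1
        ):
            # overdue: one violation, then wait for the next anchor
            self._bump(confirmed=False)
            self.last_interval = None


_AGENT_CLASSES: dict[str, type[Agent]] = {
    "always_plus": AlwaysPlus,
    "always_minus": AlwaysMinus,
    "bernoulli": Bernoulli,
    "wsls": WinStayLoseShift,
    "qlearn": QLearner,
    "regularity_seeker": RegularitySeeker,
}


def agent_init(spec: AgentSpec) -> Agent:
    """Instantiate the agent described by ``spec`` (deterministic in the spec)."""
    return _AGENT_CLASSES[spec.kind](spec)
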