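"""Per-session and group-level behavioral statistics.

The per-session measures mirror the quantities used to evaluate reward
schedules in the choice-engineering task:

* **bias fraction** -- fraction of the 100 choices made on Bias+;
* **normalized reward difference** ``(R+ - R-) / (R+ + R-)`` over *obtained*
  rewards, ranging from 1 (all rewards found on Bias+) to -1;
* **observed expectancy** -- rewards won on an option divided by the number
  of times the option was chosen: the agent's empirical payoff rate;
* **exploitation** -- rewards won on an option divided by the 25 rewards
  allocated to it: the fraction of available rewards actually discovered.

Ratios with a zero denominator (a side never chosen, no rewards obtained)
are *undefined* and reported as ``None``, never silently coerced to 0.

Group-level helpers wrap classical one-/two-sample Student t machinery,
Cohen's d, and Spearman rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .schedule import BUDGET_PER_SIDE, MINUS, PLUS
from .session import SessionResult

__all__ = [
    "MetricsSummary",
    "bias_fraction",
    "delta_rewards_norm",
    "observed_expectancy",
    "exploitation",
    "summarize_session",
    "summarize_sessions",
    "rolling_mean",
    "cohens_d_one_sample",
    "GroupCompareResult",
    "group_compare",
    "rank_correlation",
]


@dataclass(slots=True)
class MetricsSummary:
    """Derived statistics for one session; ``None`` marks undefined ratios."""

    session_id: str
    agent: str
    seed: int
    bias_plus: float
    delta_rewards_norm: Optional[float]
    expectancy_plus: Optional[float]
    expectancy_minus: Optional[float]
    exploitation_plus: float
    exploitation_minus: float
    obtained_plus: int
    obtained_minus: int
    total_obtained: int

    def as_dict(self) -> dict:
        return asdict(self)


def _counts(session: SessionResult) -> tuple[int, int, int, int]:
    """(choices+, choices-, obtained+, obtained-)."""
    c_plus = sum(1 for r in session.records if r.choice == PLUS)
    c_minus = len(session.records) - c_plus
    r_plus = sum(1 for r in session.records if r.choice == PLUS and r.obtained)
    r_minus = sum(1 for r in session.records if r.choice == MINUS and r.obtained)
    return c_plus, c_minus, r_plus, r_minus


def bias_fraction(session: SessionResult) -> float:
    """Fraction of choices on Bias+ over all trials of the session."""
    c_plus, c_minus, _, _ = _counts(session)
    return c_plus / (c_plus + c_minus)


def delta_rewards_norm(session: SessionResult) -> Optional[float]:
    """Normalized obtained-reward difference, ``(R+ - R-) / (R+ + R-)``.

    Returns ``None`` when no reward was obtained at all.
    """
    _, _, r_plus, r_minus = _counts(session)
    total = r_plus + r_minus
    if total == 0:
        return None
    return (r_plus - r_minus) / total


def observed_expectancy(session: SessionResult, side: str) -> Optional[float]:
    """Rewards obtained on ``side`` per choice of ``side``; ``None`` if never chosen."""
    if side not in (PLUS, MINUS):
        raise ValidationError(f"side must be {PLUS!r} or {MINUS!r}, got {side!r}")
    c_plus, c_minus, r_plus, r_minus = _counts(session)
    choices, rewards = (c_plus, r_plus) if side == PLUS else (c_minus, r_minus)
    if choices == 0:
        return None
    return rewards / choices


def exploitation(session: SessionResult, side: str) -> float:
    """Fraction of the 25 rewards allocated to ``side`` that were discovered."""
    if side not in (PLUS, MINUS):
        raise ValidationError(f"side must be {PLUS!r} or {MINUS!r}, got {side!r}")
    session.validate()  # requires a complete session with 25 allocations per side
    _, _, r_plus, r_minus = _counts(session)
    rewards = r_plus if side == PLUS else r_minus
    return rewards / BUDGET_PER_SIDE


def summarize_session(session: SessionResult) -> MetricsSummary:
    """All per-session metrics in one record."""
    session.validate()
    _, _, r_plus, r_minus = _counts(session)
    return MetricsSummary(
        session_id=session.session_id,
        agent=session.agent,
        seed=session.seed,
        bias_plus=bias_fraction(session),
        delta_rewards_norm=delta_rewards_norm(session),
        expectancy_plus=observed_expectancy(session, PLUS),
        expectancy_minus=observed_expectancy(session, MINUS),
        exploitation_plus=exploitation(session, PLUS),
        exploitation_minus=exploitation(session, MINUS),
        obtained_plus=r_plus,
        obtained_minus=r_minus,
        total_obtained=r_plus + r_minus,
    )


def summarize_sessions(sessions: Sequence[SessionResult]) -> pd.DataFrame:
    """Per-session metrics as a DataFrame (one row per session)."""
    return pd.DataFrame([summarize_session(s).as_dict() for s in sessions])


def rolling_mean(series: Sequence[float], window: int = 10) -> np.ndarray:
    """Trailing rolling mean with the warm-up trimmed.

    Output has length ``len(series) - window + 1``: position ``i`` is the
    mean of ``series[i : i + window]``.
    """
    values = np.asarray(series, dtype=float)
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    if window > len(values):
        raise ValidationError(
            f"window ({window}) exceeds series length ({len(values)})"
        )
    return (
        pd.Series(values).rolling(window).mean().to_numpy()[window - 1 :]
    )


def cohens_d_one_sample(values: Sequence[float], mu0: float) -> float:
    """One-sample Cohen's d: ``(mean - mu0) / s`` with the n-1 sample SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values for Cohen's d")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance: Cohen's d undefined")
    return float((x.mean() - mu0) / sd)


@dataclass(slots=True)
class GroupCompareResult:
    """Classical t-test output: statistic, df, two-tailed p, 95% CI, Cohen's d."""

    t: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    cohens_d: float

    def as_dict(self) -> dict:
        return asdict(self)


def group_compare(
    a: Sequence[float],
    b: Optional[Sequence[float]] = None,
    mu0: Optional[float] = None,
) -> GroupCompareResult:
    """One- or two-sample Student t-test with effect size.

    With ``b`` given: two-sample Student t with pooled variance, 95% CI of
    the mean difference, and Cohen's d with the pooled SD.  With ``mu0``
    given (and ``b`` omitted): one-sample t against ``mu0``, CI of
    ``mean - mu0``, and one-sample Cohen's d.  Two-tailed throughout.
    """
    x = np.asarray(a, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 values per sample")

    if b is not None:
        y = np.asarray(b, dtype=float)
        if y.size < 2:
            raise ValidationError("need at least 2 values per sample")
        nx, ny = x.size, y.size
        df = nx + ny - 2
        pooled_var = (
            (nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)
        ) / df
        if pooled_var == 0:
            raise DegenerateInputError("zero pooled variance")
        res = stats.ttest_ind(x, y, equal_var=True)
        ci = res.confidence_interval(0.95)
        d = float((x.mean() - y.mean()) / np.sqrt(pooled_var))
        return GroupCompareResult(
            t=float(res.statistic),
            df=float(df),
            p_value=float(res.pvalue),
            ci_low=float(ci.low),
            ci_high=float(ci.high),
            cohens_d=d,
        )

    if mu0 is None:
        raise ValidationError("provide either a second sample or mu0")
    if x.std(ddof=1) == 0:
        raise DegenerateInputError("zero variance in one-sample t-test")
    res = stats.ttest_1samp(x, popmean=mu0)
    ci = res.confidence_interval(0.95)
    return GroupCompareResult(
        t=float(res.statistic),
        df=float(x.size - 1),
        p_value=float(res.pvalue),
        ci_low=float(ci.low - mu0),
        ci_high=float(ci.high - mu0),
        cohens_d=cohens_d_one_sample(x, mu0),
    )


def rank_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation ``(rho, two-tailed p)``."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValidationError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValidationError("need at least 3 paired observations")
    rho, p = stats.spearmanr(xa, ya)
    return float(rho), float(p)
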