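"""Canonical session CSV, the competition-export adapter, and fixtures.

The canonical session table is a UTF-8 CSV with one row per trial and the
fixed header::

    session_id,trial,choice,alloc_plus,alloc_minus,obtained,agent,seed

``choice`` is ``P`` (Bias+) or ``M`` (Bias-); the flag columns are 0/1.
Rows are ordered by session then trial, so write -> read -> write
round-trips byte-identically.  Reading validates every structural invariant
(100 trials per session, 25 allocations per side, outcome consistency) and
rejects violations with messages naming the offending session and trial.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Sequence

from .agents import AgentSpec
from .errors import ValidationError
from .schedule import MINUS, PLUS
from .session import SessionResult, TrialRecord, derive_seed, run_session

__all__ = [
    "SESSION_COLUMNS",
    "write_sessions",
    "read_sessions",
    "read_cec_export",
    "make_fixtures",
    "FIXTURE_SCENARIOS",
]

SESSION_COLUMNS = (
    "session_id",
    "trial",
    "choice",
    "alloc_plus",
    "alloc_minus",
    "obtained",
    "agent",
    "seed",
)


def write_sessions(results: Sequence[SessionResult], path: str | Path) -> None:
    """Write sessions to the canonical CSV (stable order: session, then trial)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for res in results:
            for r in res.records:
                writer.writerow(
                    [
                        res.session_id,
                        r.trial,
                        r.choice,
                        int(r.alloc_plus),
                        int(r.alloc_minus),
                        int(r.obtained),
                        res.agent,
                        res.seed,
                    ]
                )


def _rows_to_sessions(
    rows: list[dict], *, source: str, validate: bool = True
) -> list[SessionResult]:
    """Group normalized row dicts into validated SessionResults."""
    by_session: dict[str, list[dict]] = {}
    order: list[str] = []
    for row in rows:
        sid = row["session_id"]
        if sid not in by_session:
            by_session[sid] = []
            order.append(sid)
        by_session[sid].append(row)

    results = []
    for sid in order:
        session_rows = sorted(by_session[sid], key=lambda r: r["trial"])
        records = [
            TrialRecord(
                trial=r["trial"],
                choice=r["choice"],
                alloc_plus=r["alloc_plus"],
                alloc_minus=r["alloc_minus"],
                obtained=r["obtained"],
            )
            for r in session_rows
        ]
        res = SessionResult(
            records=records,
            agent=session_rows[0].get("agent", ""),
            seed=session_rows[0].get("seed", 0),
            session_id=sid,
        )
        if validate:
            try:
                res.validate()
            except ValidationError as exc:
                raise ValidationError(f"{source}: {exc}") from exc
        results.append(res)
    return results


def _parse_flag(value: str, *, where: str) -> bool:
    if value in ("0", "1"):
        return value == "1"
    raise ValidationError(f"{where}: flag must be 0 or 1, got {value!r}")


def read_sessions(path: str | Path) -> list[SessionResult]:
    """Read and validate a canonical session CSV."""
    path = Path(path)
    rows: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in SESSION_COLUMNS if c not in header]
        if missing:
            raise ValidationError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}, session {row.get('session_id')!r}, line {lineno}"
            try:
                trial = int(row["trial"])
            except (TypeError, ValueError):
                raise ValidationError(f"{where}: bad trial index {row['trial']!r}")
            if row["choice"] not in (PLUS, MINUS):
                raise ValidationError(
                    f"{where}: choice must be {PLUS!r} or {MINUS!r}, "
                    f"got {row['choice']!r}"
                )
            rows.append(
                {
                    "session_id": row["session_id"],
                    "trial": trial,
                    "choice": row["choice"],
                    "alloc_plus": _parse_flag(row["alloc_plus"], where=where),
                    "alloc_minus": _parse_flag(row["alloc_minus"], where=where),
                    "obtained": _parse_flag(row["obtained"], where=where),
                    "agent": row["agent"],
                    "seed": int(row["seed"]),
                }
            )
    return _rows_to_sessions(rows, source=str(path))


#: Mapping keys naming the source columns of a competition export.
CEC_REQUIRED_FIELDS = (
    "session_id",
    "trial",
    "choice",
    "alloc_plus",
    "alloc_minus",
    "obtained",
)


def read_cec_export(
    path: str | Path, mapping: Mapping[str, str]
) -> list[SessionResult]:
    """Adapt a competition dataset export to canonical sessions.

    The public export's schema is not fixed, so the adapter is driven by a
    ``mapping`` from canonical field names to the export's column names.
    Required keys: ``session_id``, ``trial``, ``choice``, ``alloc_plus``,
    ``alloc_minus``, ``obtained``.  Optional keys ``choice_plus_value`` /
    ``choice_minus_value`` give the export's coding of the two sides
    (defaults ``"P"`` / ``"M"``); swapping them relabels sides consistently.
    Malformed rows raise with the row's position -- nothing is dropped
    silently.
    """
    missing = [k for k in CEC_REQUIRED_FIELDS if k not in mapping]
    if missing:
        raise ValidationError(
            f"CEC adapter mapping is missing required fields: {missing}"
        )
    plus_value = str(mapping.get("choice_plus_value", PLUS))
    minus_value = str(mapping.get("choice_minus_value", MINUS))

    path = Path(path)
    rows: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        absent = [mapping[k] for k in CEC_REQUIRED_FIELDS if mapping[k] not in header]
        if absent:
            raise ValidationError(f"{path}: export lacks mapped columns {absent}")
        for lineno, row in enumerate(reader, start=2):
            where = f"{path}, line {lineno}"
            raw_choice = str(row[mapping["choice"]])
            if raw_choice == plus_value:
                choice = PLUS
            elif raw_choice == minus_value:
                choice = MINUS
            else:
                raise ValidationError(
                    f"{where}: unrecognized choice value {raw_choice!r} "
                    f"(expected {plus_value!r} or {minus_value!r})"
                )
            try:
                rows.append(
                    {
                        "session_id": str(row[mapping["session_id"]]),
                        "trial": int(row[mapping["trial"]]),
                        "choice": choice,
                        "alloc_plus": bool(int(row[mapping["alloc_plus"]])),
                        "alloc_minus": bool(int(row[mapping["alloc_minus"]])),
                        "obtained": bool(int(row[mapping["obtained"]])),
                        "agent": "cec_participant",
                        "seed": 0,
                    }
                )
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{where}: malformed row ({exc})") from exc
    return _rows_to_sessions(rows, source=str(path))


#: Named fixture scenarios: agent spec factory per scenario.
FIXTURE_SCENARIOS: dict[str, tuple[str, dict]] = {
    "always_plus": ("always_plus", {}),
    "always_minus": ("always_minus", {}),
    # strict alternation: never stay after a miss, never stay after a win
    "alternating": ("wsls", {"stay_after_reward": 0.0, "shift_after_no_reward": 1.0}),
    "random": ("bernoulli", {"p_plus": 0.5}),
    # archetypes of strongly / moderately / weakly biased regularity seekers
    "strong_bias": ("regularity_seeker", {"commitment_gain": 0.3, "exploration_floor": 0.02}),
    "medium_bias": ("regularity_seeker", {"commitment_gain": 0.12, "exploration_floor": 0.15}),
    "weak_bias": ("regularity_seeker", {"commitment_gain": 0.04, "exploration_floor": 0.35}),
}

#: Sessions emitted per fixture scenario.
FIXTURE_SESSIONS = 3


def make_fixtures(kind: str, seed: int = 0) -> list[SessionResult]:
    """Deterministic fixture sessions for a named scenario."""
    if kind not in FIXTURE_SCENARIOS:
        raise ValidationError(
            f"unknown fixture scenario {kind!r}; "
            f"expected one of {sorted(FIXTURE_SCENARIOS)}"
        )
    agent_kind, params = FIXTURE_SCENARIOS[kind]
    spec = AgentSpec(kind=agent_kind, params=params, seed=seed)
    return [
        run_session(
            spec,
            derive_seed(seed, 0, rep),
            session_id=f"{kind}_r{rep}",
        )
        for rep in range(FIXTURE_SESSIONS)
    ]
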