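"""Reading and writing the tabular trial-log format.

The trial log is UTF-8 delimited text (CSV by default) with one row per trial
and header columns ``subject,session,trial,outcome,p_reward,iti_s,timeout_s``
plus an optional ``latency_ms`` column (blank = missing) and an optional
``cohort`` column.  Outcome labels are matched case-insensitively against the
alias table in :mod:`trialchain.outcomes` ("correct rewarded" -> R, etc.).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd

from .outcomes import parse_outcome
from .sessions import Session, SessionMeta

TextSource = Union[str, Path, IO[str]]

_REQUIRED = ("subject", "session", "trial", "outcome", "p_reward", "iti_s", "timeout_s")


class TrialLogError(ValueError):
    """Malformed or internally inconsistent trial log."""


def read_trial_log(path_or_stream: TextSource, *, sep: str = ",") -> list[Session]:
    """Parse a trial log into a list of :class:`Session`.

    Sessions are grouped by ``(subject, session)``; within a session trial
    indices must be exactly 1..n (dense, no duplicates).  Returns an empty
    list for a header-only file.

    Raises
    ------
    TrialLogError
        On missing columns, unknown outcome labels (the offending row is
        named), non-contiguous/duplicated trial indices, or a ``p_reward=1``
        session containing NR outcomes.
    """
    df = pd.read_csv(path_or_stream, sep=sep, dtype={"subject": str, "session": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise TrialLogError(f"trial log missing required columns: {missing}")
    if df.empty:
        return []

    has_latency = "latency_ms" in df.columns
    has_cohort = "cohort" in df.columns

    sessions: list[Session] = []
    # sort=False: preserve file order of session groups
    for (subject, session_id), grp in df.groupby(["subject", "session"], sort=False):
        grp = grp.sort_values("trial")
        trials = grp["trial"].to_numpy()
        if not np.array_equal(trials, np.arange(1, len(grp) + 1)):
            raise TrialLogError(
                f"subject={subject!r} session={session_id!r}: trial indices must be "
                f"contiguous 1..n without duplicates, got {trials.tolist()}"
            )
        outcomes = []
        for row_label, raw in grp["outcome"].items():
            try:
                outcomes.append(parse_outcome(raw))
            except ValueError as exc:
                raise TrialLogError(f"row {row_label + 2}: {exc}") from None

        for col in ("p_reward", "iti_s", "timeout_s"):
            if grp[col].nunique() != 1:
                raise TrialLogError(
                    f"subject={subject!r} session={session_id!r}: column {col!r} "
                    "is not constant within the session"
                )
        cohort = None
        if has_cohort:
            vals = grp["cohort"].dropna().unique()
            cohort = str(vals[0]) if len(vals) else None

        latencies = None
        if has_latency:
            lat = grp["latency_ms"].to_numpy(dtype=float)
            if not np.all(np.isnan(lat)):
                latencies = tuple(None if np.isnan(v) else float(v) for v in lat)

        meta = SessionMeta(
            subject_id=str(subject),
            session_id=str(session_id),
            p_reward=float(grp["p_reward"].iloc[0]),
            iti_s=float(grp["iti_s"].iloc[0]),
            timeout_s=float(grp["timeout_s"].iloc[0]),
            max_trials=max(len(grp), 100),
            cohort=cohort,
        )
        try:
            sessions.append(Session(meta=meta, outcomes=tuple(outcomes), latencies_ms=latencies))
        except ValueError as exc:
            raise TrialLogError(str(exc)) from None
    return sessions


def write_trial_log(
    sessions: Sequence[Session], path_or_stream: TextSource, *, sep: str = ","
) -> None:
    """Write sessions as a trial log; inverse of :func:`read_trial_log`.

    An empty session list produces a header-only file.  The ``latency_ms``
    column is emitted only if at least one session carries latencies, with
    blank fields for missing values; ``cohort`` likewise.
    """
    any_latency = any(s.latencies_ms is not None for s in sessions)
    any_cohort = any(s.meta.cohort is not None for s in sessions)
    records = []
    for s in sessions:
        for t, outcome in enumerate(s.outcomes, start=1):
            rec = {
                "subject": s.meta.subject_id,
                "session": s.meta.session_id,
                "trial": t,
                "outcome": outcome.value,
                "p_reward": s.meta.p_reward,
                "iti_s": s.meta.iti_s,
                "timeout_s": s.meta.timeout_s,
            }
            if any_latency:
                v = s.latencies_ms[t - 1] if s.latencies_ms is not None else None
                rec["latency_ms"] = np.nan if v is None else v
            if any_cohort:
                rec["cohort"] = s.meta.cohort if s.meta.cohort is not None else ""
            records.append(rec)

    columns = list(_REQUIRED)
    if any_latency:
        columns.append("latency_ms")
    if any_cohort:
        columns.append("cohort")
    df = pd.DataFrame.from_records(records, columns=columns)
    # repr-precision floats so p_reward etc. round-trip exactly
    df.to_csv(path_or_stream, sep=sep, index=False, float_format=None)


def trial_log_to_string(sessions: Sequence[Session]) -> str:
    """Serialise sessions to an in-memory trial-log string."""
    buf = _io.StringIO()
    write_trial_log(sessions, buf)
    return buf.getvalue()
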