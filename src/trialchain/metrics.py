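"""Macro-level session summaries and impulsivity screening.

``summarize_session`` tallies the five outcome types per session (the
dependent variables of the macro analyses); ``classify_impulsivity``
implements the quartile screen that labels animals HI (highest-impulsive,
strictly above the 75th percentile of mean premature responding), LI
(strictly below the 25th) or MID (everything else, including boundary ties).
Percentiles use numpy's linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .outcomes import CANONICAL_ORDER, OUTCOME_INDEX, Outcome
from .sessions import Session


@dataclass(frozen=True)
class SessionSummary:
    """Per-outcome tallies for one session."""

    subject_id: str
    session_id: str
    counts: tuple[int, int, int, int, int]  # canonical order
    n_trials: int
    mean_correct_latency_ms: Optional[float] = None

    @property
    def premature_count(self) -> int:
        return self.counts[OUTCOME_INDEX[Outcome.PREMATURE]]


@dataclass(frozen=True)
class ImpulsivityScreen:
    """One subject's screening result."""

    subject_id: str
    mean_premature: float
    label: str  # "HI" | "MID" | "LI"


def summarize_session(session: Session) -> SessionSummary:
    """Exact outcome tallies; latency mean over R/NR trials when present."""
    codes = session.outcome_codes
    counts = tuple(int(c) for c in np.bincount(codes, minlength=len(CANONICAL_ORDER)))
    mean_lat = None
    if session.latencies_ms is not None:
        vals = [
            v
            for v, c in zip(session.latencies_ms, codes)
            if v is not None and c in (0, 1)
        ]
        if vals:
            mean_lat = float(np.mean(vals))
    return SessionSummary(
        subject_id=session.meta.subject_id,
        session_id=session.meta.session_id,
        counts=counts,
        n_trials=len(session),
        mean_correct_latency_ms=mean_lat,
    )


def classify_impulsivity(
    mean_premature_by_subject: Mapping[str, float],
) -> list[ImpulsivityScreen]:
    """Quartile split of subjects by mean premature responding.

    Strictly above the 75th percentile -> HI; strictly below the 25th -> LI;
    all others (including values equal to a boundary) -> MID.  Requires at
    least 4 subjects.  The labelling is invariant to subject order and
    monotone in each subject's mean.
    """
    if len(mean_premature_by_subject) < 4:
        raise ValueError("impulsivity screening requires >= 4 subjects")
    values = np.asarray(list(mean_premature_by_subject.values()), dtype=float)
    q25, q75 = np.percentile(values, [25, 75])  # linear interpolation
    out = []
    for subject, v in mean_premature_by_subject.items():
        label = "HI" if v > q75 else ("LI" if v < q25 else "MID")
        out.append(ImpulsivityScreen(subject_id=subject, mean_premature=float(v), label=label))
    return out


def screening_means(
    sessions: Sequence[Session], session_ids: Optional[Sequence[str]] = None
) -> dict[str, float]:
    """Per-subject mean premature count over the screening sessions.

    ``session_ids`` selects which sessions count as challenge sessions (all
    sessions if None); the screening structure lives in the data, not here.
    """
    wanted = set(session_ids) if session_ids is not None else None
    per_subject: dict[str, list[int]] = {}
    for s in sessions:
        if wanted is not None and s.meta.session_id not in wanted:
            continue
        per_subject.setdefault(s.meta.subject_id, []).append(
            summarize_session(s).premature_count
        )
    return {subj: float(np.mean(v)) for subj, v in per_subject.items()}


def premature_latency_correlation(
    summaries: Sequence[SessionSummary],
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between premature counts and latencies.

    Mirrors the macro-level correlation between premature responding and
    correct-response latency; needs >= 3 summaries with a latency and
    nonzero variance in both variables.
    """
    pairs = [
        (s.premature_count, s.mean_correct_latency_ms)
        for s in summaries
        if s.mean_correct_latency_ms is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need >= 3 summaries with latency for a correlation")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a variable")
    r, p = stats.pearsonr(x.astype(float), y.astype(float))
    return float(r), float(p)
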