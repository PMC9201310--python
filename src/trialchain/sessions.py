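"""Session containers: an ordered outcome sequence plus schedule metadata.

A *session* is the unit of all estimation: one animal performing up to
``max_trials`` trials under a fixed reinforcement probability ``p_reward``,
inter-trial interval and time-out.  Trial indices are 1-based and dense.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .outcomes import OUTCOME_INDEX, Outcome


@dataclass(frozen=True)
class SessionMeta:
    """Schedule metadata attached to one session.

    Parameters
    ----------
    subject_id, session_id : str
        Opaque identifiers; ``(subject_id, session_id)`` keys a session.
    p_reward : float
        Probability that a correct response is rewarded, in (0, 1].
    iti_s : float
        Inter-trial interval in seconds (> 0).
    timeout_s : float
        Time-out punishment duration in seconds (> 0).
    max_trials : int
        Session cap on the number of trials (>= 1).
    cohort : str, optional
        Free-form cohort tag.
    """

    subject_id: str
    session_id: str
    p_reward: float
    iti_s: float
    timeout_s: float
    max_trials: int = 100
    cohort: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_reward <= 1.0):
            raise ValueError(f"p_reward must be in (0, 1], got {self.p_reward}")
        if self.iti_s <= 0:
            raise ValueError(f"iti_s must be > 0, got {self.iti_s}")
        if self.timeout_s <= 0:
            raise ValueError(f"timeout_s must be > 0, got {self.timeout_s}")
        if self.max_trials < 1:
            raise ValueError(f"max_trials must be >= 1, got {self.max_trials}")


@dataclass(frozen=True)
class Session:
    """One session's ordered trial outcomes (1-based trial index ``t``)."""

    meta: SessionMeta
    outcomes: tuple[Outcome, ...]
    latencies_ms: Optional[tuple[Optional[float], ...]] = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        if not (1 <= len(self.outcomes) <= self.meta.max_trials):
            raise ValueError(
                f"session length {len(self.outcomes)} outside "
                f"[1, max_trials={self.meta.max_trials}]"
            )
        if self.meta.p_reward == 1.0 and Outcome.NR in self.outcomes:
            raise ValueError(
                "session with p_reward=1 cannot contain NR outcomes "
                f"(subject={self.meta.subject_id!r}, session={self.meta.session_id!r})"
            )
        if self.latencies_ms is not None:
            lat = tuple(self.latencies_ms)
            object.__setattr__(self, "latencies_ms", lat)
            if len(lat) != len(self.outcomes):
                raise ValueError("latencies_ms must match outcomes in length")
            for v in lat:
                if v is not None and v < 0:
                    raise ValueError(f"negative latency {v}")

    def __len__(self) -> int:
        return len(self.outcomes)

    @property
    def outcome_codes(self) -> np.ndarray:
        """Outcomes as canonical-order integer codes (shape ``(n,)``)."""
        return np.fromiter(
            (OUTCOME_INDEX[o] for o in self.outcomes), dtype=np.intp, count=len(self)
        )


def as_sessions(session_or_sessions: Session | Sequence[Session]) -> list[Session]:
    """Normalise a single session or an iterable of sessions to a list."""
    if isinstance(session_or_sessions, Session):
        return [session_or_sessions]
    sessions = list(session_or_sessions)
    if not all(isinstance(s, Session) for s in sessions):
        raise TypeError("expected Session instances")
    return sessions
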