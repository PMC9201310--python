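import numpy as np
import pytest

from trialchain import Outcome, Session, SessionMeta

#: The 12-outcome worked sequence used across estimation tests.
SEQ12 = [
    "NR", "premature", "premature", "R", "NR", "premature",
    "omission", "R", "R", "incorrect", "NR", "NR",
]


def make_meta(
    subject="rat01",
    session="base",
    p_reward=0.5,
    iti_s=5.0,
    timeout_s=5.0,
    max_trials=100,
    cohort=None,
):
    return SessionMeta(
        subject_id=subject,
        session_id=session,
        p_reward=p_reward,
        iti_s=iti_s,
        timeout_s=timeout_s,
        max_trials=max_trials,
        cohort=cohort,
    )


def make_session(labels, latencies=None, **meta_kwargs):
    meta_kwargs.setdefault("max_trials", max(100, len(labels)))
    return Session(
        meta=make_meta(**meta_kwargs),
        outcomes=tuple(Outcome(x) if isinstance(x, Outcome) else Outcome(x) for x in labels),
        latencies_ms=latencies,
    )


@pytest.fixture
def seq12_session():
    return make_session(SEQ12)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)
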