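"""Synthetic 5CSRTT sessions with the task's outcome structure.

Two layers:

* a *behaviour policy* emits one of four actions per trial — correct,
  incorrect, omission, premature — either independently of history
  (``independence`` kind) or conditioned on the previous trial *outcome*
  (``first_order`` kind, 5 conditioning states so that R vs NR history can
  influence the next action);
* a *task layer* turns actions into outcomes: incorrect/omission/premature
  actions map to their like-named outcomes, while each correct action
  consumes the next slot of a blockwise pseudo-randomised reward schedule
  and becomes R if the slot is rewarded, NR otherwise.

The reward schedule is built in blocks of 20 trials (configurable), each
block containing exactly ``round(block_size * p_reward)`` rewarded slots in
seeded-random order, emulating partial-reinforcement sessions with
``p(R)`` in {0.2, 0.5, 0.8, 1}.  Everything is reproducible from seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .outcomes import CANONICAL_ORDER, N_STATES, Outcome
from .sessions import Session, SessionMeta

#: Action order used by every probability vector in this module.
ACTIONS: tuple[str, ...] = ("correct", "incorrect", "omission", "premature")

# Action index -> outcome code for the three actions with a fixed outcome
# (correct resolves to R/NR through the schedule).
_ACTION_TO_OUTCOME = {1: 3, 2: 4, 3: 2}  # incorrect, omission, premature

#: Baseline action mix: ~87% accuracy among responses, 10% omissions, 15%
#: prematures — a stable well-trained rat under standard task parameters.
DEFAULT_ACTION_PROBS: tuple[float, ...] = (0.65, 0.10, 0.10, 0.15)

_ATOL = 1e-12


def _check_probs(vec: np.ndarray, what: str) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (len(ACTIONS),):
        raise ValueError(f"{what} must have length {len(ACTIONS)}")
    if (vec < 0).any() or (vec > 1).any() or abs(vec.sum() - 1.0) > _ATOL * len(ACTIONS):
        raise ValueError(f"{what} must be a probability vector summing to 1")
    return vec


@dataclass(frozen=True)
class BehaviorPolicy:
    """Generative stand-in for the animal.

    ``independence`` policies draw every action from ``action_probs``;
    ``first_order`` policies draw the action at trial ``t`` from the row of
    ``conditional_probs`` indexed by the outcome of trial ``t - 1`` (rows in
    canonical outcome order), with ``initial_action_probs`` for trial 1.
    """

    kind: str = "independence"
    action_probs: Optional[np.ndarray] = None
    conditional_probs: Optional[np.ndarray] = None
    initial_action_probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in ("independence", "first_order"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "independence":
            ap = self.action_probs if self.action_probs is not None else DEFAULT_ACTION_PROBS
            ap = _check_probs(np.asarray(ap, float), "action_probs")
            object.__setattr__(self, "action_probs", ap)
            init = self.initial_action_probs if self.initial_action_probs is not None else ap
        else:
            if self.conditional_probs is None:
                raise ValueError("first_order policy requires conditional_probs")
            cp = np.asarray(self.conditional_probs, dtype=float)
            if cp.shape != (N_STATES, len(ACTIONS)):
                raise ValueError(f"conditional_probs must be {N_STATES}x{len(ACTIONS)}")
            for i in range(N_STATES):
                _check_probs(cp[i], f"conditional_probs row {CANONICAL_ORDER[i]}")
            object.__setattr__(self, "conditional_probs", cp)
            init = (
                self.initial_action_probs
                if self.initial_action_probs is not None
                else cp.mean(axis=0)
            )
        object.__setattr__(
            self, "initial_action_probs", _check_probs(np.asarray(init, float), "initial_action_probs")
        )

    @property
    def premature_propensity(self) -> float:
        """Marginal-ish probability of a premature action (crude, for latency coupling)."""
        if self.kind == "independence":
            return float(self.action_probs[ACTIONS.index("premature")])
        return float(self.conditional_probs[:, ACTIONS.index("premature")].mean())


def independence_policy(
    action_probs: Sequence[float] = DEFAULT_ACTION_PROBS,
) -> BehaviorPolicy:
    """History-free policy (the null the diagnostics should *not* reject)."""
    return BehaviorPolicy(kind="independence", action_probs=np.asarray(action_probs, float))


def premature_carryover_policy(
    base_action_probs: Sequence[float] = DEFAULT_ACTION_PROBS,
    excess: float = 0.25,
    nr_excess: float = 0.0,
) -> BehaviorPolicy:
    """First-order policy with elevated premature responding after specific outcomes.

    After a premature outcome the premature-action probability is raised by
    ``excess`` above the baseline (other actions rescaled); ``nr_excess``
    does the same after an NR outcome, emulating invigoration by reward
    omission.  All other rows keep the baseline mix.
    """
    base = _check_probs(np.asarray(base_action_probs, float), "base_action_probs")
    j = ACTIONS.index("premature")
    rows = np.tile(base, (N_STATES, 1))

    def _boost(row: np.ndarray, extra: float) -> np.ndarray:
        new_p = row[j] + extra
        if not (0.0 <= new_p <= 1.0):
            raise ValueError(f"boosted premature probability {new_p} outside [0, 1]")
        out = row * (1.0 - new_p) / (1.0 - row[j])
        out[j] = new_p
        return out

    rows[CANONICAL_ORDER.index(Outcome.PREMATURE)] = _boost(base, excess)
    if nr_excess:
        rows[CANONICAL_ORDER.index(Outcome.NR)] = _boost(base, nr_excess)
    return BehaviorPolicy(kind="first_order", conditional_probs=rows, initial_action_probs=base)


@dataclass(frozen=True)
class ScheduleConfig:
    """Blockwise pseudo-randomised partial-reinforcement schedule."""

    p_reward: float
    n_trials: int
    block_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_reward <= 1.0):
            raise ValueError(f"p_reward must be in (0, 1], got {self.p_reward}")
        if self.n_trials < 1 or self.block_size < 1:
            raise ValueError("n_trials and block_size must be positive")

    @property
    def rewards_per_block(self) -> int:
        return int(round(self.block_size * self.p_reward))


@dataclass(frozen=True)
class LatencyModel:
    """Lognormal correct-response latencies with an impulsivity-coupled mean.

    ``log latency ~ Normal(log(base_ms) + premature_coupling * policy
    premature propensity, sigma)``; only R/NR trials get a latency.  This is
    plumbing for macro-level correlation checks, not a behavioural claim.
    """

    base_ms: float = 500.0
    sigma: float = 0.15
    premature_coupling: float = 0.0


def make_reward_schedule(
    config: ScheduleConfig, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Boolean reward slots, one per *correct action* the policy will emit.

    The array is a concatenation of ``ceil(n_trials / block_size)`` blocks,
    each holding exactly ``round(block_size * p_reward)`` True values in
    seeded-random order; deterministic given ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_blocks = math.ceil(config.n_trials / config.block_size)
    k = config.rewards_per_block
    blocks = []
    for _ in range(n_blocks):
        block = np.zeros(config.block_size, dtype=bool)
        block[:k] = True
        rng.shuffle(block)
        blocks.append(block)
    return np.concatenate(blocks)


def simulate_session(
    policy: BehaviorPolicy,
    meta: SessionMeta,
    schedule: ScheduleConfig,
    latency: Optional[LatencyModel] = None,
) -> Session:
    """Draw one session: policy actions resolved through the reward schedule.

    Session length is ``min(schedule.n_trials, meta.max_trials)``.  Fully
    reproducible from ``schedule.seed`` (schedule shuffling, action draws and
    optional latencies use independent child streams).
    """
    if meta.p_reward != schedule.p_reward:
        raise ValueError(
            f"meta.p_reward={meta.p_reward} != schedule.p_reward={schedule.p_reward}"
        )
    ss_sched, ss_act, ss_lat = np.random.SeedSequence(schedule.seed).spawn(3)
    rewards = make_reward_schedule(schedule, rng=np.random.default_rng(ss_sched))
    n = min(schedule.n_trials, meta.max_trials)
    rng = np.random.default_rng(ss_act)

    if policy.kind == "independence":
        actions = rng.choice(len(ACTIONS), size=n, p=policy.action_probs)
    else:
        cum = np.cumsum(policy.conditional_probs, axis=1)
        cum_init = np.cumsum(policy.initial_action_probs)
        u = rng.random(n)
        actions = np.empty(n, dtype=np.intp)
        actions[0] = np.searchsorted(cum_init, u[0], side="right")
        prev_outcome = -1  # filled below trial by trial

    codes = np.empty(n, dtype=np.intp)
    n_correct = 0
    for t in range(n):
        if policy.kind == "first_order" and t > 0:
            actions[t] = np.searchsorted(cum[prev_outcome], u[t], side="right")
        a = int(actions[t])
        if a == 0:  # correct: consume one reward slot
            codes[t] = 0 if rewards[n_correct] else 1
            n_correct += 1
        else:
            codes[t] = _ACTION_TO_OUTCOME[a]
        if policy.kind == "first_order":
            prev_outcome = codes[t]

    outcomes = tuple(CANONICAL_ORDER[c] for c in codes)
    latencies = None
    if latency is not None:
        lat_rng = np.random.default_rng(ss_lat)
        mu = math.log(latency.base_ms) + latency.premature_coupling * policy.premature_propensity
        draws = lat_rng.lognormal(mean=mu, sigma=latency.sigma, size=n)
        latencies = tuple(
            float(draws[t]) if codes[t] in (0, 1) else None for t in range(n)
        )
    return Session(meta=meta, outcomes=outcomes, latencies_ms=latencies)


def _perturb_policy(
    policy: BehaviorPolicy, sd: float, rng: np.random.Generator
) -> BehaviorPolicy:
    """Seeded log-odds perturbation of every probability vector, renormalised."""
    if sd == 0.0:
        return policy

    def _jitter(vec: np.ndarray) -> np.ndarray:
        logits = np.log(np.clip(vec, 1e-12, None)) + rng.normal(0.0, sd, size=vec.shape)
        z = np.exp(logits - logits.max())
        return z / z.sum()

    if policy.kind == "independence":
        return BehaviorPolicy(
            kind="independence",
            action_probs=_jitter(policy.action_probs),
            initial_action_probs=_jitter(policy.initial_action_probs),
        )
    rows = np.vstack([_jitter(r) for r in policy.conditional_probs])
    return BehaviorPolicy(
        kind="first_order",
        conditional_probs=rows,
        initial_action_probs=_jitter(policy.initial_action_probs),
    )


def simulate_cohort(
    n_subjects: int,
    base_policy: BehaviorPolicy,
    between_subject_sd: float,
    metas: Sequence[SessionMeta],
    master_seed: int,
    block_size: int = 20,
    latency: Optional[LatencyModel] = None,
) -> list[Session]:
    """Simulate ``n_subjects`` animals, one session per condition in ``metas``.

    Each subject's policy is the base policy with seeded logit-scale
    perturbations of scale ``between_subject_sd`` (shared across that
    subject's conditions).  Deterministic under ``master_seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if between_subject_sd < 0:
        raise ValueError("between_subject_sd must be >= 0")
    sessions: list[Session] = []
    for k, subj_ss in enumerate(np.random.SeedSequence(master_seed).spawn(n_subjects)):
        rng = np.random.default_rng(subj_ss)
        policy = _perturb_policy(base_policy, between_subject_sd, rng)
        for m, meta in enumerate(metas):
            meta_k = replace(
                meta,
                subject_id=f"sub{k:03d}",
                session_id=meta.session_id or f"cond{m:02d}",
            )
            sched = ScheduleConfig(
                p_reward=meta.p_reward,
                n_trials=meta.max_trials,
                block_size=block_size,
                seed=int(rng.integers(2**31)),
            )
            sessions.append(simulate_session(policy, meta_k, sched, latency=latency))
    return sessions
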