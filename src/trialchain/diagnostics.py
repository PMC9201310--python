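"""Order diagnostics for the trial-outcome chain.

Three tests of the independence (zeroth-order) model against the observed
first-order structure:

* ``w_statistic`` — the likelihood-ratio statistic
  ``W = 2 * sum_ij O_ij * ln(O_ij / E_ij)`` (the G statistic for contingency
  tables), referred to chi-square with ``(S-1)^2 = 16`` degrees of freedom.
* ``chi2_into_state`` — a restricted Pearson chi-square on the single column
  of transitions *into* a target state (premature, by default), referred to
  chi-square with 5 degrees of freedom.
* ``y_deviation`` — per-start-state standardized residuals
  ``Y[i] = (O[i, target] - E[i, target]) / sqrt(E[i, target])``; positive Y
  means the transition happens more often than independence predicts.

The decision rule is the fixed-critical-value rule (reject iff the statistic
exceeds the upper-alpha chi-square quantile); p-values are reported alongside
for convenience but do not drive the ``reject`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimation import (
    IndependenceFit,
    TransitionCounts,
    TransitionMatrix,
    count_transitions,
    estimate_first_order,
    estimate_zeroth_order,
)
from .outcomes import CANONICAL_ORDER, N_STATES, OUTCOME_INDEX, Outcome
from .sessions import Session, as_sessions

#: Degrees of freedom of the full-table test for an S-state chain.
FULL_TABLE_DOF: int = (N_STATES - 1) ** 2


@dataclass(frozen=True)
class TestResult:
    """A chi-square-referred test with the fixed-critical-value rule."""

    statistic: float
    dof: int
    alpha: float
    critical_value: float
    p_value: float
    reject: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "reject" if self.reject else "retain"
        return (
            f"stat={self.statistic:.2f}, dof={self.dof}, "
            f"crit({self.alpha})={self.critical_value:.2f}, p={self.p_value:.4g} "
            f"-> {verdict} independence"
        )


@dataclass(frozen=True)
class DeviationProfile:
    """Standardized residuals of transitions into ``target_state``.

    ``y`` follows the canonical start-state order; entries where the expected
    frequency is zero are NaN and flagged False in ``defined``.
    """

    target_state: Outcome
    y: np.ndarray
    defined: np.ndarray


@dataclass(frozen=True)
class SplitHalfReport:
    """Homogeneity check: per-half fits and their disagreement.

    ``max_abs_diff_into_target`` is the largest absolute difference between
    the two halves' transition probabilities into the target state, over
    start states defined in both halves (0 with ``degenerate=True`` when no
    start state is defined in both).
    """

    first_half: tuple[TransitionMatrix, TestResult]
    second_half: tuple[TransitionMatrix, TestResult]
    target_state: Outcome
    max_abs_diff_into_target: float
    degenerate: bool = False


def chi2_critical(alpha: float, dof: int) -> float:
    """Upper-``alpha`` quantile of the chi-square distribution with ``dof``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if dof < 1:
        raise ValueError(f"dof must be >= 1, got {dof}")
    return float(stats.chi2.ppf(1.0 - alpha, dof))


def _make_result(statistic: float, dof: int, alpha: float) -> TestResult:
    crit = chi2_critical(alpha, dof)
    return TestResult(
        statistic=float(statistic),
        dof=dof,
        alpha=alpha,
        critical_value=crit,
        p_value=float(stats.chi2.sf(statistic, dof)),
        reject=bool(statistic > crit),
    )


def w_statistic(
    counts: TransitionCounts, fit: IndependenceFit, alpha: float = 0.05
) -> TestResult:
    """Likelihood-ratio (G) test of independence on the full table.

    Cells with ``O == 0`` contribute nothing (``0 * ln 0 = 0`` convention);
    a cell with ``E == 0`` but ``O > 0`` makes the ratio undefined and is an
    error.  Degrees of freedom are ``(S - 1)^2``.
    """
    O = counts.counts.astype(float)
    E = fit.expected
    bad = (E == 0) & (O > 0)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"degenerate table: observed {int(O[i, j])} transitions "
            f"{CANONICAL_ORDER[i]}->{CANONICAL_ORDER[j]} but expected frequency is 0"
        )
    mask = O > 0
    W = 2.0 * float(np.sum(O[mask] * np.log(O[mask] / E[mask])))
    return _make_result(W, FULL_TABLE_DOF, alpha)


def chi2_into_state(
    counts: TransitionCounts,
    fit: IndependenceFit,
    target: Outcome,
    alpha: float = 0.05,
    dof: int = 5,
) -> TestResult:
    """Restricted Pearson chi-square on transitions into ``target``.

    ``sum_i (O[i, target] - E[i, target])^2 / E[i, target]`` over start
    states with positive expected frequency; 5 degrees of freedom by default.

    Raises
    ------
    ValueError
        If the target state is never expected (all ``E[:, target] == 0``).
    """
    j = OUTCOME_INDEX[Outcome(target)]
    O = counts.counts[:, j].astype(float)
    E = fit.expected[:, j]
    ok = E > 0
    if not ok.any():
        raise ValueError(f"target state {target} has zero expected frequency everywhere")
    if ((~ok) & (O > 0)).any():
        raise ValueError("observed transitions into target where expected frequency is 0")
    statistic = float(np.sum((O[ok] - E[ok]) ** 2 / E[ok]))
    return _make_result(statistic, dof, alpha)


def y_deviation(
    counts: TransitionCounts, fit: IndependenceFit, target: Outcome
) -> DeviationProfile:
    """Per-start-state standardized residuals into ``target``."""
    j = OUTCOME_INDEX[Outcome(target)]
    O = counts.counts[:, j].astype(float)
    E = fit.expected[:, j]
    defined = E > 0
    y = np.full(N_STATES, np.nan)
    y[defined] = (O[defined] - E[defined]) / np.sqrt(E[defined])
    return DeviationProfile(target_state=Outcome(target), y=y, defined=defined)


def _half_analysis(
    halves: Sequence[Session], alpha: float
) -> tuple[TransitionMatrix, TestResult, TransitionCounts]:
    counts = count_transitions(halves, pool=True)
    if counts.n_transitions == 0:
        raise ValueError("a session half has zero transitions")
    fit = estimate_zeroth_order(counts)
    return estimate_first_order(counts), w_statistic(counts, fit, alpha), counts


def split_half_homogeneity(
    session_or_pool: Session | Sequence[Session],
    target: Outcome = Outcome.PREMATURE,
    alpha: float = 0.05,
) -> SplitHalfReport:
    """Compare first-order fits between session halves.

    Each session of length ``n`` is split at ``floor(n / 2)`` — no transition
    spans the split — and the two pools of halves are fitted assuming
    homogeneity within each half.  Sessions shorter than 4 trials are
    excluded with a warning.
    """
    sessions = as_sessions(session_or_pool)
    usable = [s for s in sessions if len(s) >= 4]
    if len(usable) < len(sessions):
        warnings.warn(
            f"excluded {len(sessions) - len(usable)} session(s) shorter than 4 "
            "trials from split-half analysis",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no session with >= 4 trials for split-half analysis")

    firsts, seconds = [], []
    for s in usable:
        cut = len(s) // 2
        firsts.append(Session(meta=s.meta, outcomes=s.outcomes[:cut]))
        seconds.append(Session(meta=s.meta, outcomes=s.outcomes[cut:]))

    P1, test1, _ = _half_analysis(firsts, alpha)
    P2, test2, _ = _half_analysis(seconds, alpha)

    j = OUTCOME_INDEX[Outcome(target)]
    both = P1.defined_rows & P2.defined_rows
    degenerate = not both.any()
    if degenerate:
        warnings.warn(
            "no start state defined in both halves; reporting max_abs_diff = 0",
            stacklevel=2,
        )
        diff = 0.0
    else:
        diff = float(np.max(np.abs(P1.probs[both, j] - P2.probs[both, j])))
    return SplitHalfReport(
        first_half=(P1, test1),
        second_half=(P2, test2),
        target_state=Outcome(target),
        max_abs_diff_into_target=diff,
        degenerate=degenerate,
    )
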