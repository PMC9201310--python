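"""First-order and zeroth-order (independence) model estimation.

The first-order chain is summarised by the S x S transition-frequency table
``O[i, j]`` — the number of adjacent trial pairs with outcome ``i`` at trial
``t-1`` and outcome ``j`` at trial ``t`` — and the row-normalised transition
probabilities ``P[i, j] = O[i, j] / row_total[i]``.  The zeroth-order
(independence) model assumes ``P(X_t = j | X_{t-1}) = p[j]`` regardless of
history; its expected transition frequencies are the outer product
``E[i, j] = p[j] * row_total[i]``, which with the end-margin estimate of
``p`` reduces to ``E[i, j] = col_total[j] * row_total[i] / n_transitions``.

Transitions never span a session boundary; pooling across sessions (or
animals) sums the per-session tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .outcomes import CANONICAL_ORDER, N_STATES, OUTCOME_INDEX, Outcome
from .sessions import Session, as_sessions

Margin = Literal["start", "end", "all-trials"]

_ATOL_PROB = 1e-12
_ATOL_FREQ = 1e-9


@dataclass(frozen=True)
class TransitionCounts:
    """Observed transition frequencies pooled over one or more sessions.

    Attributes
    ----------
    counts : (S, S) int array
        ``counts[i, j]`` = number of pairs ``(X_{t-1}=i, X_t=j)``.
    n_transitions : int
        Total adjacent pairs, ``sum(n_k - 1)`` over sessions.
    start_totals : (S,) int array
        Per-state occurrences over trials ``1..n-1`` (row margins).
    end_totals : (S,) int array
        Per-state occurrences over trials ``2..n`` (column margins).
    state_totals : (S,) int array
        Per-state occurrences over *all* trials, kept so the all-trials
        denominator variant is computable from the counts object alone.
    """

    counts: np.ndarray
    n_transitions: int
    start_totals: np.ndarray
    end_totals: np.ndarray
    state_totals: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "start_totals", np.asarray(self.start_totals, dtype=np.int64))
        object.__setattr__(self, "end_totals", np.asarray(self.end_totals, dtype=np.int64))
        object.__setattr__(self, "state_totals", np.asarray(self.state_totals, dtype=np.int64))
        if c.shape != (N_STATES, N_STATES) or (c < 0).any():
            raise ValueError("counts must be a nonnegative SxS matrix")
        if c.sum() != self.n_transitions:
            raise ValueError("cell sum must equal n_transitions")
        if not np.array_equal(c.sum(axis=1), self.start_totals):
            raise ValueError("row sums must equal start_totals")
        if not np.array_equal(c.sum(axis=0), self.end_totals):
            raise ValueError("column sums must equal end_totals")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic first-order transition probabilities.

    Rows whose start state never occurs carry NaN and are flagged in
    ``defined_rows`` rather than imputed.
    """

    probs: np.ndarray
    defined_rows: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        d = np.asarray(self.defined_rows, dtype=bool)
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "defined_rows", d)
        if p.shape != (N_STATES, N_STATES) or d.shape != (N_STATES,):
            raise ValueError("bad shapes for TransitionMatrix")
        rows = p[d]
        if rows.size:
            if np.nanmin(rows) < -_ATOL_PROB or np.nanmax(rows) > 1 + _ATOL_PROB:
                raise ValueError("probabilities outside [0, 1]")
            if not np.allclose(rows.sum(axis=1), 1.0, rtol=0, atol=_ATOL_PROB * N_STATES):
                raise ValueError("defined rows must sum to 1")


@dataclass(frozen=True)
class IndependenceFit:
    """Zeroth-order state probabilities and expected transition frequencies."""

    state_probs: np.ndarray
    expected: np.ndarray
    margin: Margin = "end"

    def __post_init__(self) -> None:
        p = np.asarray(self.state_probs, dtype=float)
        e = np.asarray(self.expected, dtype=float)
        object.__setattr__(self, "state_probs", p)
        object.__setattr__(self, "expected", e)
        if p.shape != (N_STATES,) or e.shape != (N_STATES, N_STATES):
            raise ValueError("bad shapes for IndependenceFit")
        if abs(p.sum() - 1.0) > _ATOL_PROB * N_STATES:
            raise ValueError("state_probs must sum to 1")


def count_transitions(
    sessions: Session | Sequence[Session], *, pool: bool = True
) -> TransitionCounts | list[TransitionCounts]:
    """Tally adjacent-pair transition frequencies.

    With ``pool=True`` (default) per-session tables are summed; no pair is
    ever formed across a session boundary.  With ``pool=False`` a list of
    per-session :class:`TransitionCounts` is returned.

    Raises
    ------
    ValueError
        If the session list is empty.
    """
    sessions = as_sessions(sessions)
    if not sessions:
        raise ValueError("count_transitions requires at least one session")
    if not pool:
        return [count_transitions(s, pool=True) for s in sessions]

    counts = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    state_totals = np.zeros(N_STATES, dtype=np.int64)
    for s in sessions:
        codes = s.outcome_codes
        state_totals += np.bincount(codes, minlength=N_STATES)
        if codes.size >= 2:
            np.add.at(counts, (codes[:-1], codes[1:]), 1)
    return TransitionCounts(
        counts=counts,
        n_transitions=int(counts.sum()),
        start_totals=counts.sum(axis=1),
        end_totals=counts.sum(axis=0),
        state_totals=state_totals,
    )


def estimate_first_order(counts: TransitionCounts) -> TransitionMatrix:
    """Row-normalise a count table into transition probabilities.

    ``P[i, j] = O[i, j] / start_totals[i]`` where the row total is positive;
    never-visited start states yield undefined (NaN, flagged) rows.
    """
    defined = counts.start_totals > 0
    probs = np.full((N_STATES, N_STATES), np.nan)
    if defined.any():
        probs[defined] = counts.counts[defined] / counts.start_totals[defined, None]
    return TransitionMatrix(probs=probs, defined_rows=defined)


def estimate_zeroth_order(counts: TransitionCounts, *, margin: Margin = "end") -> IndependenceFit:
    """Fit the independence (zeroth-order) model to a count table.

    ``state_probs`` is the chosen margin normalised to 1 — ``"end"``
    (default) uses trials 2..n and reproduces the product formula
    ``E[i, j] = end_totals[j] * start_totals[i] / n_transitions``; ``"start"``
    uses trials 1..n-1; ``"all-trials"`` uses every trial.  Expected
    frequencies preserve the observed row margins exactly.

    Raises
    ------
    ValueError
        If the table has no transitions.
    """
    if counts.n_transitions == 0:
        raise ValueError("cannot fit independence model with zero transitions")
    if margin == "end":
        totals = counts.end_totals
    elif margin == "start":
        totals = counts.start_totals
    elif margin == "all-trials":
        totals = counts.state_totals
    else:
        raise ValueError(f"unknown margin {margin!r}")
    state_probs = totals / totals.sum()
    expected = np.outer(counts.start_totals.astype(float), state_probs)
    fit = IndependenceFit(state_probs=state_probs, expected=expected, margin=margin)
    assert abs(expected.sum() - counts.n_transitions) < _ATOL_FREQ * max(1, counts.n_transitions)
    return fit


class FirstOrderMarkov(BaseEstimator):
    """First-order Markov chain estimator over the five trial outcomes.

    Scikit-learn style: ``fit`` consumes sessions, fitted state lives in
    trailing-underscore attributes.

    Attributes
    ----------
    counts_ : TransitionCounts
        Pooled observed transition frequencies.
    transition_matrix_ : TransitionMatrix
        Row-normalised transition probabilities.
    states_ : tuple of Outcome
        Canonical state order indexing all matrices.
    """

    def fit(self, X: Session | Sequence[Session], y: None = None) -> "FirstOrderMarkov":
        self.counts_ = count_transitions(X, pool=True)
        self.transition_matrix_ = estimate_first_order(self.counts_)
        self.states_ = CANONICAL_ORDER
        return self

    def predict_proba(self, X: Sequence[Outcome]) -> np.ndarray:
        """Next-outcome distribution for each previous outcome in ``X``."""
        self._check_fitted()
        idx = [OUTCOME_INDEX[Outcome(o)] for o in X]
        return self.transition_matrix_.probs[idx]

    def _check_fitted(self) -> None:
        if not hasattr(self, "transition_matrix_"):
            raise AttributeError("estimator is not fitted; call fit() first")


class IndependenceModel(BaseEstimator):
    """Zeroth-order (history-free) model of trial outcomes.

    Parameters
    ----------
    margin : {"end", "start", "all-trials"}
        Which trial margin estimates the state probabilities (see
        :func:`estimate_zeroth_order`).

    Attributes
    ----------
    counts_ : TransitionCounts
    fit_ : IndependenceFit
    state_probs_ : (S,) array
    expected_ : (S, S) array
        Expected transition frequencies under independence.
    """

    def __init__(self, margin: Margin = "end") -> None:
        self.margin = margin

    def fit(self, X: Session | Sequence[Session], y: None = None) -> "IndependenceModel":
        self.counts_ = count_transitions(X, pool=True)
        self.fit_ = estimate_zeroth_order(self.counts_, margin=self.margin)
        self.state_probs_ = self.fit_.state_probs
        self.expected_ = self.fit_.expected
        self.states_ = CANONICAL_ORDER
        return self
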