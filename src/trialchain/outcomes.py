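"""Trial outcome state space of the 5CSRTT Markov chain.

Every completed trial of the five-choice serial reaction time task ends in
exactly one of five states: correct rewarded (R), correct non-rewarded (NR),
premature, incorrect, or omission.  Under partial reinforcement a correct
response is rewarded only with probability ``p(R)``, which is what splits
"correct" into R and NR.  These five labels are the states ``X_t`` of the
first-order chain; all matrices in the package are indexed in the canonical
order below.
"""

from __future__ import annotations

from enum import Enum


class Outcome(str, Enum):
    """One of the five possible end states of a 5CSRTT trial."""

    R = "R"
    NR = "NR"
    PREMATURE = "premature"
    INCORRECT = "incorrect"
    OMISSION = "omission"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical state ordering used for every matrix row/column in the package.
CANONICAL_ORDER: tuple[Outcome, ...] = (
    Outcome.R,
    Outcome.NR,
    Outcome.PREMATURE,
    Outcome.INCORRECT,
    Outcome.OMISSION,
)

#: Number of states S of the chain.
N_STATES: int = len(CANONICAL_ORDER)

#: Outcome -> matrix index in canonical order.
OUTCOME_INDEX: dict[Outcome, int] = {o: i for i, o in enumerate(CANONICAL_ORDER)}

#: Labels in canonical order, for matrix headers.
OUTCOME_LABELS: tuple[str, ...] = tuple(o.value for o in CANONICAL_ORDER)

# Accepted spellings for each outcome.  Matching is case-insensitive and
# collapses runs of whitespace/underscores/hyphens to single spaces.
_ALIASES: dict[str, Outcome] = {
    "r": Outcome.R,
    "correct rewarded": Outcome.R,
    "rewarded": Outcome.R,
    "nr": Outcome.NR,
    "correct non rewarded": Outcome.NR,
    "correct nonrewarded": Outcome.NR,
    "non rewarded": Outcome.NR,
    "nonrewarded": Outcome.NR,
    "premature": Outcome.PREMATURE,
    "incorrect": Outcome.INCORRECT,
    "omission": Outcome.OMISSION,
}


def parse_outcome(label: str) -> Outcome:
    """Map a textual outcome label to its canonical :class:`Outcome`.

    Raises
    ------
    ValueError
        If the label is not in the alias table (e.g. ``"reward"``).
    """
    if isinstance(label, Outcome):
        return label
    key = " ".join(str(label).strip().lower().replace("-", " ").replace("_", " ").split())
    try:
        return _ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown outcome label {label!r}; expected one of "
            f"{sorted(set(_ALIASES))}"
        ) from None
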