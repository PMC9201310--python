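"""Independent brute-force oracles for the Markov diagnostics.

Deliberately naive pure-Python implementations (dict/loop based, no numpy
vectorisation) so they share no code path with the package.
"""

import math

S = 5  # canonical order: R, NR, premature, incorrect, omission


def pair_counts(codes):
    """Exhaustive enumeration of adjacent pairs in one coded sequence."""
    table = [[0] * S for _ in range(S)]
    for a, b in zip(codes, codes[1:]):
        table[a][b] += 1
    return table


def pooled_pair_counts(sequences):
    table = [[0] * S for _ in range(S)]
    for codes in sequences:
        t = pair_counts(codes)
        for i in range(S):
            for j in range(S):
                table[i][j] += t[i][j]
    return table


def row_totals(table):
    return [sum(row) for row in table]


def col_totals(table):
    return [sum(table[i][j] for i in range(S)) for j in range(S)]


def transition_probs(table):
    """Row-normalised probabilities; None rows where the start state is unseen."""
    out = []
    for row in table:
        tot = sum(row)
        out.append(None if tot == 0 else [c / tot for c in row])
    return out


def expected_independence(table):
    """End-margin product formula E[i][j] = col[j] * row[i] / n."""
    n = sum(row_totals(table))
    cols = col_totals(table)
    rows = row_totals(table)
    return [[cols[j] * rows[i] / n for j in range(S)] for i in range(S)]


def g_statistic(observed, expected):
    """2 * sum O * ln(O / E), zero-observed cells skipped."""
    total = 0.0
    for i in range(S):
        for j in range(S):
            o = observed[i][j]
            if o > 0:
                total += o * math.log(o / expected[i][j])
    return 2.0 * total


def pearson_chi2_column(observed, expected, j):
    """Restricted Pearson statistic over column j, rows with E > 0."""
    total = 0.0
    for i in range(S):
        e = expected[i][j]
        if e > 0:
            total += (observed[i][j] - e) ** 2 / e
    return total


def y_column(observed, expected, j):
    """Standardized residuals of column j; None where E == 0."""
    out = []
    for i in range(S):
        e = expected[i][j]
        out.append(None if e == 0 else (observed[i][j] - e) / math.sqrt(e))
    return out
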