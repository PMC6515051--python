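"""Independent oracles used by the tests: brute-force alignment enumeration
and exact Wilcoxon sign-assignment enumeration.  Deliberately naive and
separate from the implementations they check."""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_global(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best global alignment score by exhaustive path enumeration (no memo);
    a gap run of length g costs gap_open + g * gap_extend."""

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            best = max(best, matrix[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "M")


def brute_force_local(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best local score = best global score over any substring pair, floored
    at zero (the empty alignment)."""
    best = 0.0
    for i1, i2 in itertools.combinations(range(len(a) + 1), 2):
        for j1, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(
                best,
                brute_force_global(a[i1:i2], b[j1:j2], matrix, gap_open, gap_extend),
            )
    return best


def exact_wilcoxon_p(d: np.ndarray) -> float:
    """Two-sided signed-rank p by full enumeration of all 2^n sign
    assignments (zero differences dropped; assumes no |d| ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    sums = np.array(
        [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product((0, 1), repeat=n)
        ]
    )
    cdf = float(np.mean(sums <= w_obs))
    sf = float(np.mean(sums >= w_obs))
    return min(1.0, 2.0 * min(cdf, sf))
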