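"""Independent oracles used by the tests.

These deliberately take different computational routes from the package:
a true brute-force path enumerator and a memoized top-down recursion for
affine-gap alignment scores, Biopython's C aligner as a third route, and
a matrix-exponential one-site Markov chain for substitution expectations.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.linalg
from Bio import Align

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 5.0, -4.0, 10.0, 0.5


def score_columns(cols) -> float:
    """Affine score of an explicit alignment given as (a_char|None,
    b_char|None) columns; each maximal gap run pays open + len*extend,
    and adjacent runs of different gap kinds each pay their own opening."""
    score = 0.0
    prev = None
    for ac, bc in cols:
        if ac is None or bc is None:
            kind = "D" if ac is None else "I"
            if kind != prev:
                score -= GAP_OPEN
            score -= GAP_EXT
            prev = kind
        else:
            prev = None
            score += MATCH if ac == bc else MISMATCH
    return score


def brute_force_optimum(a: str, b: str) -> float:
    """Enumerate every global alignment (use only for len <= ~6)."""
    best = [-np.inf]

    def walk(i: int, j: int, cols):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_columns(cols))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + [(a[i], b[j])])
        if j < len(b):
            walk(i, j + 1, cols + [(None, b[j])])
        if i < len(a):
            walk(i + 1, j, cols + [(a[i], None)])

    walk(0, 0, [])
    return best[0]


def memoized_optimum(a: str, b: str) -> float:
    """Top-down recursion over (i, j, last-op) covering the full alignment
    space with sharing; independent of the package's bottom-up DP."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if j < len(b):
            cost = GAP_EXT + (GAP_OPEN if state != "D" else 0.0)
            best = max(best, -cost + rec(i, j + 1, "D"))
        if i < len(a):
            cost = GAP_EXT + (GAP_OPEN if state != "I" else 0.0)
            best = max(best, -cost + rec(i + 1, j, "I"))
        return best

    return rec(0, 0, "S")


def biopython_score(a: str, b: str) -> float:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXT)
    aligner.extend_gap_score = -GAP_EXT
    return float(aligner.score(a, b))


def hky_expected_p(time_myr: float, rate: float, kappa: float) -> float:
    """Expected p-distance of one site after `time_myr` under the HKY
    chain with uniform base frequencies (transition partner = base XOR 2
    in the package's coding; here built from scratch)."""
    b = rate / (kappa + 2.0)
    a_ = kappa * b
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = a_ if (i ^ 2) == j else b
        Q[i, i] = -Q[i].sum()
    P = scipy.linalg.expm(Q * time_myr)
    return float(1.0 - np.mean(np.diag(P)))
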