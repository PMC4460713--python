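"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: alignment scores come
from exhaustive enumeration of all global alignments, hypergeometric and
Hardy-Weinberg probabilities from exact integer/rational arithmetic, and the
trend statistic from the N*r^2 identity on reconstructed individual-level
data.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import pearsonr

GAP = "-"


def enumerate_alignments(a: str, b: str):
    """All global alignments of a and b (no gap-vs-gap columns)."""
    if not a and not b:
        yield ("", "")
        return
    if a and b:
        for x, y in enumerate_alignments(a[1:], b[1:]):
            yield (a[0] + x, b[0] + y)
    if a:
        for x, y in enumerate_alignments(a[1:], b):
            yield (a[0] + x, GAP + y)
    if b:
        for x, y in enumerate_alignments(a, b[1:]):
            yield (GAP + x, b[0] + y)


def score_alignment(aa, bb, matrix, gap_open, gap_extend, penalize_end_gaps):
    score = 0.0
    for ca, cb in zip(aa, bb):
        if ca != GAP and cb != GAP:
            score += matrix[ca, cb]
    n = len(aa)
    for s in (aa, bb):
        i = 0
        while i < n:
            if s[i] != GAP:
                i += 1
                continue
            j = i
            while j < n and s[j] == GAP:
                j += 1
            if penalize_end_gaps or (i != 0 and j != n):
                score -= gap_open + (j - i - 1) * gap_extend
            i = j
    return score


def best_alignment_score(a, b, matrix, gap_open=10.0, gap_extend=0.5, penalize_end_gaps=False):
    return max(
        score_alignment(aa, bb, matrix, gap_open, gap_extend, penalize_end_gaps)
        for aa, bb in enumerate_alignments(a, b)
    )


def hypergeom_upper_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k), exact rational arithmetic."""
    num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return Fraction(num, math.comb(N, n))


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> Fraction:
    """Exact conditional Hardy-Weinberg p-value, integer weights."""
    n = n_AA + n_Aa + n_aa
    nm = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    weights = {}
    for h in range(nm % 2, nm + 1, 2):
        hom_m = (nm - h) // 2
        weights[h] = math.comb(n, hom_m) * math.comb(n - hom_m, h) * 2**h
    total = sum(weights.values())
    obs = weights[n_Aa]
    return Fraction(sum(w for w in weights.values() if w <= obs), total)


def catt_chi2_oracle(r0, r1, r2, s0, s1, s2) -> float:
    """Trend chi-square via the N * r^2 identity on individual-level data."""
    g = np.concatenate(
        [np.full(c, v, dtype=float) for v, c in zip((0, 1, 2, 0, 1, 2), (r0, r1, r2, s0, s1, s2))]
    )
    y = np.concatenate([np.ones(r0 + r1 + r2), np.zeros(s0 + s1 + s2)])
    r, _ = pearsonr(g, y)
    return len(g) * r**2
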