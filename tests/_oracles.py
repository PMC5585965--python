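"""Independent brute-force oracles used by the tests.

These are deliberately naive re-derivations (pure-Python DP, explicit
combinatorial sums, step-up-by-definition BH) kept separate from the
package so each check runs along two independent routes.
"""

from __future__ import annotations

from math import comb

import numpy as np


def sw_affine_score(a: str, b: str, match=1, mismatch=-2, gap_open=-4, gap_extend=-3) -> int:
    """Exhaustive affine-gap Smith-Waterman best local score (Gotoh recursion).

    A gap of length L costs gap_open + (L-1)*gap_extend; N scores 0 against
    anything. O(len(a)*len(b)) with explicit loops — for tiny strings only.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in a (consuming b)
    f = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == "N" or b[j - 1] == "N":
                s = 0
            elif a[i - 1] == b[j - 1]:
                s = match
            else:
                s = mismatch
            e[i][j] = max(h[i][j - 1] + gap_open, e[i][j - 1] + gap_extend)
            f[i][j] = max(h[i - 1][j] + gap_open, f[i - 1][j] + gap_extend)
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            if h[i][j] > best:
                best = h[i][j]
    return int(best)


def hypergeom_upper_tail(x: int, big_m: int, k_set: int, k_draw: int) -> float:
    """P(X >= x) for X ~ Hypergeom(universe big_m, successes k_set, draws k_draw),
    by explicit summation of binomial-coefficient ratios."""
    denom = comb(big_m, k_draw)
    total = 0
    for i in range(x, min(k_set, k_draw) + 1):
        if k_draw - i > big_m - k_set:
            continue
        total += comb(k_set, i) * comb(big_m - k_set, k_draw - i)
    return total / denom


def min_prefix_p(ranked: list[str], members: set[str], universe_size: int) -> tuple[float, int]:
    """Brute-force min-over-all-prefixes ordered-enrichment statistic.

    Evaluates the hypergeometric upper tail at *every* prefix length
    (not only at member positions) and returns (p_min, smallest argmin k).
    """
    k_set = len(members)
    best_p, best_k = 1.0, 0
    for k in range(1, len(ranked) + 1):
        x = sum(1 for s in ranked[:k] if s in members)
        if x == 0:
            continue
        p = hypergeom_upper_tail(x, universe_size, k_set, k)
        if p < best_p - 1e-15:
            best_p, best_k = p, k
    return best_p, best_k


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the step-up definition, O(m^2)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        # q_i = min over all p_j >= p_i of p_j * m / rank(p_j)
        candidates = [
            pj * m / (np.sum(p <= pj)) for pj in p if pj >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q
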