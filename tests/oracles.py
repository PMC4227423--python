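"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles (integer combinatorics,
literal definitions, exhaustive enumeration) and deliberately shares no
code with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        q[order[i]] = min(1.0, np.min(ranked[i:]))
    return q


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by integer enumeration over the margin.

    Sums the point probabilities of every table with the observed margins
    whose (integer, exact) probability weight does not exceed the observed
    table's weight.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(r1 + r2, c1)
    w_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            total += w
    return total / denom


def hypergeom_tail_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact integer summation of the pmf."""
    denom = comb(N, n)
    lo = max(0, n + K - N)
    hi = min(K, n)
    if k <= lo:
        return 1.0
    total = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1))
    return total / denom


def hypergeom_tail_by_subsets(k_obs: int, N: int, M: int, n: int) -> float:
    """P(X >= k_obs) by exhaustive enumeration of all n-subsets of N items.

    The first M items are "marked"; a subset counts when it contains at
    least k_obs marked items. Only feasible for small N.
    """
    hits = 0
    total = 0
    for subset in combinations(range(N), n):
        total += 1
        if sum(1 for i in subset if i < M) >= k_obs:
            hits += 1
    return hits / total if total else 1.0


def ease_oracle(overlap: int, query: int, set_size: int, universe: int) -> float:
    """EASE score from the exact tail oracle with the decremented overlap."""
    return hypergeom_tail_oracle(max(overlap - 1, 0), universe, set_size, query)
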