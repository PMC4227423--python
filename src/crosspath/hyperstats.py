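"""Exact hypergeometric tail probabilities in log space.

Both the over-representation statistic (EASE score) and the pathway-pair
interaction statistic reduce to an upper tail of the hypergeometric
distribution: drawing ``n`` items from a universe of ``N`` containing ``K``
marked items, the probability of seeing at least ``k`` marked draws. The
tail is summed from log-gamma binomial coefficients, which is exact to
double precision over the whole range of counts this pipeline produces and
keeps the implementation independent of any library distribution object
(library routines serve as cross-checks in the test suite).
"""

from __future__ import annotations

from math import exp, inf, lgamma

__all__ = ["log_binom", "hypergeom_pmf", "hypergeom_upper_tail"]


def log_binom(n: int, k: int) -> float:
    """log C(n, k); -inf outside the valid range."""
    if k < 0 or k > n or n < 0:
        return -inf
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n)."""
    log_p = log_binom(K, k) + log_binom(N - K, n - k) - log_binom(N, n)
    return 0.0 if log_p == -inf else exp(log_p)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters must satisfy ``0 <= K <= N`` and ``0 <= n <= N``. Values of
    ``k`` at or below the distribution's support minimum give exactly 1.
    """
    if N < 0 or not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    lo = max(0, n + K - N)
    hi = min(K, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    # sum the shorter tail for accuracy
    upper_terms = hi - k + 1
    lower_terms = k - lo
    if upper_terms <= lower_terms:
        total = sum(hypergeom_pmf(j, N, K, n) for j in range(k, hi + 1))
        return min(1.0, total)
    total = sum(hypergeom_pmf(j, N, K, n) for j in range(lo, k))
    return min(1.0, max(0.0, 1.0 - total))
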