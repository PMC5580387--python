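"""Independent brute-force oracles used by the test suite.

Everything here is exact rational arithmetic (math.comb + Fraction) or naive
search, deliberately sharing no code with the package implementations.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache


def hypergeom_pmf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact hypergeometric point probability via integer binomials."""
    if k < 0 or k > K or n - k < 0 or n - k > N - K:
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


@lru_cache(maxsize=None)
def _conditional_pmf(row1: int, row2: int, col1: int) -> dict[int, Fraction]:
    """Exact distribution of cell a over all tables with the given margins."""
    N = row1 + row2
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    return {x: hypergeom_pmf_exact(x, N, col1, row1) for x in range(lo, hi + 1)}


def fisher_exact_bruteforce(a: int, b: int, c: int, d: int) -> tuple[Fraction, Fraction]:
    """(one-sided, two-sided) Fisher p-values by exhaustive table enumeration.

    Enumerates every 2x2 table with the observed margins; the one-sided p is
    the smaller tail at the observed cell, the two-sided p sums the point
    probabilities of all tables no more probable than the observed one.
    """
    pmf = _conditional_pmf(a + b, c + d, a + c)
    p_obs = pmf[a]
    p_lower = sum(p for x, p in pmf.items() if x <= a)
    p_upper = sum(p for x, p in pmf.items() if x >= a)
    p_one = min(p_lower, p_upper, Fraction(1))
    p_two = min(sum(p for p in pmf.values() if p <= p_obs), Fraction(1))
    return p_one, p_two


def binom_tail_geq(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def clopper_pearson_bisect(
    k: int, n: int, level: float = 0.95, tol: float = 1e-12
) -> tuple[float, float]:
    """Exact central binomial CI by bisection on the binomial tails."""
    tail = (1 - level) / 2

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
            if hi - lo < tol:
                break
        return (lo + hi) / 2

    # lower bound: largest p with P(X >= k | p) <= tail
    low = 0.0 if k == 0 else bisect(lambda p: binom_tail_geq(k, n, p) - tail, 0.0, 1.0)
    # upper bound: smallest p with P(X <= k | p) <= tail
    high = (
        1.0
        if k == n
        else bisect(lambda p: tail - (1 - binom_tail_geq(k + 1, n, p)), 0.0, 1.0)
    )
    return low, high


def conditional_or_grid(a: int, b: int, c: int, d: int) -> float:
    """Conditional-likelihood odds ratio by golden-section search on log(psi)."""
    row1, col1 = a + b, a + c
    N = row1 + c + d
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    xs = range(lo, hi + 1)
    base = {x: float(hypergeom_pmf_exact(x, N, col1, row1)) for x in xs}

    def negloglik(log_psi: float) -> float:
        weights = [base[x] * math.exp(x * log_psi) for x in xs]
        return -(math.log(base[a]) + a * log_psi - math.log(sum(weights)))

    gr = (math.sqrt(5) - 1) / 2
    left, right = -30.0, 30.0
    x1 = right - gr * (right - left)
    x2 = left + gr * (right - left)
    f1, f2 = negloglik(x1), negloglik(x2)
    for _ in range(300):
        if f1 < f2:
            right, x2, f2 = x2, x1, f1
            x1 = right - gr * (right - left)
            f1 = negloglik(x1)
        else:
            left, x1, f1 = x1, x2, f2
            x2 = left + gr * (right - left)
            f2 = negloglik(x2)
    return math.exp((left + right) / 2)


def all_tables_with_margins_leq(max_margin: int):
    """Every 2x2 count table whose four margins are all <= max_margin."""
    for a in range(max_margin + 1):
        for b in range(max_margin + 1 - a):
            for c in range(max_margin + 1 - a):
                for d in range(max_margin + 1 - max(b, c)):
                    if a + b + c + d == 0:
                        continue
                    if b + d <= max_margin and c + d <= max_margin:
                        yield a, b, c, d
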