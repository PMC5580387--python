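"""Exact small-sample inference for incidence comparisons.

Everything here is built from first principles on top of the hypergeometric
distribution: the PMF is evaluated in log-space, Fisher's exact test
enumerates the conditional distribution directly (two-sided p by the
minimum-likelihood rule, which is what standard statistical software
reports), the binomial confidence interval is the exact central
Clopper-Pearson interval, and the odds ratio is the conditional maximum
likelihood estimate under the noncentral hypergeometric model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist

from .classifier import Identity
from .errors import UndefinedStatisticError

DEFAULT_ALPHA = 0.05
DEFAULT_CI_LEVEL = 0.95

# Relative slack when comparing point probabilities in the minimum-likelihood
# two-sided rule, so ties are not broken by floating-point noise (same
# convention as R's fisher.test).
_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = populations and columns = outcome (event vs non-event)."""

    a: int  # row 1, event
    b: int  # row 1, non-event
    c: int  # row 2, event
    d: int  # row 2, non-event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col1(self) -> int:
        return self.a + self.c

    @property
    def col2(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class IncidenceResult:
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_level: float = DEFAULT_CI_LEVEL
    method: str = "clopper-pearson"

    def format_percent(self, decimals: int = 1) -> str:
        return f"{round_half_up(100 * self.proportion, decimals)}%"


@dataclass(frozen=True)
class ExactTestResult:
    table: ContingencyTable2x2
    p_one_sided: float
    p_two_sided: float
    odds_ratio: float
    or_method: str = "conditional-mle"
    alpha: float = DEFAULT_ALPHA
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero at the reported digit (not banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeometric(N, K, n); -inf outside support."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < max(0, n - (N - K)) or k > min(n, K):
        return -math.inf
    lg = math.lgamma
    return (
        lg(K + 1) - lg(k + 1) - lg(K - k + 1)
        + lg(N - K + 1) - lg(n - k + 1) - lg(N - K - n + k + 1)
        - (lg(N + 1) - lg(n + 1) - lg(N - n + 1))
    )


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) drawing n without replacement from N containing K successes."""
    return math.exp(log_hypergeom_pmf(k, N, K, n))


def _support(t: ContingencyTable2x2) -> range:
    """Support of cell ``a`` when all margins are fixed."""
    lo = max(0, t.row1 - t.col2)
    hi = min(t.row1, t.col1)
    return range(lo, hi + 1)


def fisher_exact(
    t: ContingencyTable2x2, alpha: float = DEFAULT_ALPHA
) -> ExactTestResult:
    """Fisher's exact test by full enumeration of the conditional distribution.

    One-sided p is the tail probability in the observed direction (the smaller
    of the lower and upper tails at the observed cell).  Two-sided p sums the
    probabilities of all tables whose point probability does not exceed the
    observed one (minimum-likelihood rule).
    """
    support = _support(t)
    if len(support) == 1:
        return ExactTestResult(
            table=t,
            p_one_sided=1.0,
            p_two_sided=1.0,
            odds_ratio=odds_ratio(t),
            alpha=alpha,
            note="degenerate margin: conditional distribution is a point mass",
        )

    N, K, n = t.total, t.col1, t.row1
    pmf = {x: hypergeom_pmf(x, N, K, n) for x in support}
    p_obs = pmf[t.a]

    p_lower = sum(p for x, p in pmf.items() if x <= t.a)
    p_upper = sum(p for x, p in pmf.items() if x >= t.a)
    p_one = min(1.0, min(p_lower, p_upper))

    cutoff = p_obs * (1.0 + _REL_TOL)
    included = [p for p in pmf.values() if p <= cutoff]
    # observed table is the mode => every table counts => exactly 1
    p_two = 1.0 if len(included) == len(pmf) else min(1.0, sum(included))

    return ExactTestResult(
        table=t,
        p_one_sided=p_one,
        p_two_sided=p_two,
        odds_ratio=odds_ratio(t),
        alpha=alpha,
    )


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Conditional maximum-likelihood odds ratio (noncentral hypergeometric).

    Diverges to +inf (or collapses to 0) when the observed cell sits at the
    edge of its conditional support.
    """
    support = _support(t)
    lo, hi = support[0], support[-1]
    if lo == hi:
        return math.nan  # degenerate: odds ratio not identifiable
    if t.a == hi:
        return math.inf
    if t.a == lo:
        return 0.0

    N, K, n = t.total, t.col1, t.row1
    base = [log_hypergeom_pmf(x, N, K, n) for x in support]
    xs = list(support)

    def cond_mean_minus_a(log_psi: float) -> float:
        logw = [b + x * log_psi for b, x in zip(base, xs)]
        logz = logsumexp(logw)
        mean = sum(x * math.exp(lw - logz) for x, lw in zip(xs, logw))
        return mean - t.a

    # E[X | psi] is strictly increasing in psi; bracket then solve.
    lo_b, hi_b = -1.0, 1.0
    while cond_mean_minus_a(lo_b) > 0:
        lo_b *= 2
        if lo_b < -500:  # pragma: no cover - guarded by edge cases above
            return 0.0
    while cond_mean_minus_a(hi_b) < 0:
        hi_b *= 2
        if hi_b > 500:  # pragma: no cover
            return math.inf
    log_psi = brentq(cond_mean_minus_a, lo_b, hi_b, xtol=1e-12)
    return math.exp(log_psi)


def incidence(k: int, n: int, ci_level: float = DEFAULT_CI_LEVEL) -> IncidenceResult:
    """Proportion k/n with an exact central Clopper-Pearson interval."""
    if n < 1:
        raise UndefinedStatisticError("incidence undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n], got k={k}, n={n}")
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    tail = (1 - ci_level) / 2
    low = 0.0 if k == 0 else float(beta_dist.ppf(tail, k, n - k + 1))
    high = 1.0 if k == n else float(beta_dist.ppf(1 - tail, k + 1, n - k))
    return IncidenceResult(
        k=k, n=n, proportion=k / n, ci_low=low, ci_high=high, ci_level=ci_level
    )


@dataclass(frozen=True)
class IncidenceComparison:
    incidence_a: IncidenceResult
    incidence_b: IncidenceResult
    test: ExactTestResult
    excluded_a: dict[str, int] = field(default_factory=dict)
    excluded_b: dict[str, int] = field(default_factory=dict)


def _group_counts(calls: pd.DataFrame) -> tuple[int, int, dict[str, int]]:
    """(#C/T, #C7, exclusions) from a classify_dataset frame."""
    idents = calls["identity"]
    n_ct = int((idents == Identity.CT.value).sum())
    n_c7 = int((idents == Identity.C7.value).sum())
    excluded = {
        ident.value: int((idents == ident.value).sum())
        for ident in (Identity.T1, Identity.INDETERMINATE)
        if int((idents == ident.value).sum())
    }
    return n_ct, n_c7, excluded


def compare_incidence(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> IncidenceComparison:
    """Exact comparison of C/T incidence between two classified datasets.

    The per-group denominator is #C7 + #C/T; T1 and indeterminate calls are
    excluded and their counts reported.
    """
    ct_a, c7_a, excl_a = _group_counts(calls_a)
    ct_b, c7_b, excl_b = _group_counts(calls_b)
    if ct_a + c7_a == 0 or ct_b + c7_b == 0:
        raise UndefinedStatisticError(
            "comparison undefined: a group has no C7 or C/T calls after exclusions"
        )
    table = ContingencyTable2x2(ct_a, c7_a, ct_b, c7_b)
    return IncidenceComparison(
        incidence_a=incidence(ct_a, ct_a + c7_a, ci_level),
        incidence_b=incidence(ct_b, ct_b + c7_b, ci_level),
        test=fisher_exact(table, alpha=alpha),
        excluded_a=excl_a,
        excluded_b=excl_b,
    )


def format_p(p: float, decimals: int = 3) -> str:
    return f"{round_half_up(p, decimals):.{decimals}f}"
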