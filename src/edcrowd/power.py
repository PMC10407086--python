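"""Exact sample-size calculation for Fisher's exact test on two proportions.

The study-design question: how many visits per group are needed so that a
two-sided Fisher's exact test at level ``alpha`` detects a difference
between event proportions ``p1`` and ``p2`` with the requested power?  Power
is computed exactly by enumerating both binomial margins (truncated where
the tail mass drops below 1e-12), not by a normal approximation.  Exact
tests have a saw-toothed power curve in ``n``; the search therefore stops at
the smallest ``n`` for which the target power is reached at both ``n`` and
``n + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, SearchError

__all__ = ["SampleSizeResult", "exact_power", "fisher_sample_size"]

_TAIL_EPS = 1e-12
_REL_TOL = 1.0 + 1e-7  # tie tolerance when summing "as or less probable" tables


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest per-group size meeting the power target, and the total.

    ``per_group`` is the number of subjects in each of the two equal groups;
    ``total`` is ``2 * per_group`` (a "visits needed" statement may refer to
    either convention, so both are reported).
    """

    per_group: int
    total: int
    achieved_power: float


def _two_sided_pvalues(m: int, n: int) -> np.ndarray:
    """Two-sided Fisher p-values for all tables with margin ``m`` successes
    out of two groups of size ``n``.

    Returns p-values indexed by ``x1 - lo`` where ``lo = max(0, m - n)``;
    the two-sided p-value sums the probabilities of all tables no more
    probable than the observed one (the standard convention).
    """
    lo = max(0, m - n)
    hi = min(n, m)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, 2 * n, m, n)
    order = np.argsort(pmf)
    sorted_pmf = pmf[order]
    cum = np.cumsum(sorted_pmf)
    # p(x) = sum of pmf over tables with pmf <= pmf(x) (with tie tolerance)
    idx = np.searchsorted(sorted_pmf, pmf * _REL_TOL, side="right") - 1
    return np.minimum(cum[np.maximum(idx, 0)], 1.0)


def exact_power(n: int, p1: float, p2: float, alpha: float) -> float:
    """Exact power of the two-sided Fisher test with *n* per group.

    Enumerates both binomial margins, truncating each at the point where the
    remaining tail mass is below 1e-12.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    x1_max = int(stats.binom.isf(_TAIL_EPS / 10, n, p1)) + 1
    x2_max = int(stats.binom.isf(_TAIL_EPS / 10, n, p2)) + 1
    x1_max, x2_max = min(x1_max, n), min(x2_max, n)
    b1 = stats.binom.pmf(np.arange(x1_max + 1), n, p1)
    b2 = stats.binom.pmf(np.arange(x2_max + 1), n, p2)
    power = 0.0
    for m in range(0, x1_max + x2_max + 1):
        lo = max(0, m - n)
        x1_lo = max(lo, m - x2_max)
        x1_hi = min(x1_max, m)
        if x1_lo > x1_hi:
            continue
        pvals = _two_sided_pvalues(m, n)
        x1 = np.arange(x1_lo, x1_hi + 1)
        reject = pvals[x1 - lo] <= alpha
        power += float(np.sum(b1[x1] * b2[m - x1] * reject))
    return power


def fisher_sample_size(
    p1: float,
    p2: float,
    power: float = 0.8,
    alpha: float = 0.05,
    max_per_group: int = 1_000_000,
) -> SampleSizeResult:
    """Smallest equal per-group *n* reaching the target exact power.

    Because exact-test power is saw-toothed rather than monotone, the
    stopping rule is smoothed: the returned *n* is the smallest for which
    the power target is met at both *n* and *n + 1*.  Raises
    :class:`SearchError` when the target is unreachable within the bound
    (in particular for ``p1 == p2``, where power never exceeds ``alpha``).
    """
    for name, v in (("p1", p1), ("p2", p2)):
        if not 0.0 < v < 1.0:
            raise DomainError(f"{name} must be in (0, 1)")
    if not 0.0 < power < 1.0 or not 0.0 < alpha < 1.0:
        raise DomainError("power and alpha must be in (0, 1)")
    if p1 == p2:
        raise SearchError("p1 == p2: power never exceeds alpha, no finite n")

    # normal-approximation pilot to start the bracket near the answer
    za = stats.norm.isf(alpha / 2.0)
    zb = stats.norm.isf(1.0 - power)
    var = p1 * (1 - p1) + p2 * (1 - p2)
    n0 = max(2, int(np.ceil((za + zb) ** 2 * var / (p1 - p2) ** 2)))

    n_hi = max(2, n0 // 2)
    last_power = exact_power(n_hi, p1, p2, alpha)
    while last_power < power:
        if n_hi >= max_per_group:
            raise SearchError(
                f"target power {power} not reached within n = {max_per_group} per group"
            )
        n_hi = min(2 * n_hi, max_per_group)
        last_power = exact_power(n_hi, p1, p2, alpha)

    # bisect toward the approximate boundary, then scan for the smoothed stop
    lo, hi = 2, n_hi
    while lo < hi:
        mid = (lo + hi) // 2
        if exact_power(mid, p1, p2, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    n = lo
    for _ in range(1000):
        pw_n = exact_power(n, p1, p2, alpha)
        if pw_n >= power and exact_power(n + 1, p1, p2, alpha) >= power:
            return SampleSizeResult(per_group=n, total=2 * n, achieved_power=pw_n)
        n += 1
        if n > max_per_group:
            break
    raise SearchError("smoothed stopping rule not satisfied within the search cap")
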