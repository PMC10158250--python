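"""Coupon-collector analytics for library saturation.

A prey library built from m colonies with inserts drawn uniformly over a
space of S = 4**k sequences is "saturated" when every insert is represented.
These routines quantify that design argument: the expected number of
distinct inserts after m draws, and the probability that all S inserts were
drawn at least once — exactly (by inclusion-exclusion in rational
arithmetic) for small spaces, and by the Poisson approximation
exp(-S (1 - 1/S)**m) for large ones.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import NamedTuple

__all__ = ["expected_distinct", "prob_all_covered", "CoverageProbability"]

#: Largest space size for which the inclusion-exclusion sum is evaluated
#: exactly; beyond it the Poisson approximation is used.
EXACT_S_MAX = 64


def expected_distinct(m: int, S: int) -> float:
    """Expected number of distinct inserts among m uniform draws from S.

    Closed form S (1 - (1 - 1/S)**m), evaluated via expm1/log1p so it stays
    accurate when m is large and the coverage approaches S.
    """
    if m < 0 or S < 1:
        raise ValueError("need m >= 0 and S >= 1")
    if m == 0:
        return 0.0
    if S == 1:
        return 1.0
    return -S * math.expm1(m * math.log1p(-1.0 / S))


class CoverageProbability(NamedTuple):
    value: float
    method: str  # "exact", "series" or "poisson"


def _coverage_series(m: int, S: int) -> CoverageProbability:
    """Large-S evaluation of the inclusion-exclusion sum in log space.

    The expected number of uncovered inserts is mu = S (1 - 1/S)**m.  When
    mu <= 16 the alternating terms C(S, j) (1 - j/S)**m stay below ~e**mu, so
    summing them as floats (each term evaluated via lgamma and log1p) keeps
    the absolute error near machine precision; the sum is truncated once
    terms fall below 1e-18.  When mu > 16 the coverage probability is below
    ~1.2e-7 and the Poisson approximation exp(-mu) is returned instead
    (absolute error smaller than the value itself), labeled as approximate.
    """
    log_q = m * math.log1p(-1.0 / S)
    mu = S * math.exp(log_q)
    if mu > 16.0:
        return CoverageProbability(math.exp(-mu), "poisson")
    total = 1.0
    sign = -1.0
    for j in range(1, S + 1):
        log_term = (
            math.lgamma(S + 1)
            - math.lgamma(j + 1)
            - math.lgamma(S - j + 1)
            + m * math.log1p(-j / S)
        )
        if log_term < -41.5:  # term < ~1e-18; remainder is negligible
            break
        total += sign * math.exp(log_term)
        sign = -sign
    return CoverageProbability(min(max(total, 0.0), 1.0), "series")


def prob_all_covered(m: int, S: int) -> CoverageProbability:
    """Probability that m uniform draws cover all S inserts at least once.

    Exact for S <= 64 via the inclusion-exclusion sum
    sum_j (-1)**j C(S, j) (1 - j/S)**m, computed in rational arithmetic so
    the alternating cancellation is exact; for larger S the same sum is
    evaluated in log space with alternating-sum care (see
    :func:`_coverage_series`), degrading to the Poisson approximation — and
    labeled as such — only where the probability is below ~1e-7.
    """
    if m < 0 or S < 1:
        raise ValueError("need m >= 0 and S >= 1")
    if m < S:
        return CoverageProbability(0.0, "exact")  # pigeonhole
    if S <= EXACT_S_MAX:
        total = 0
        for j in range(S + 1):
            term = math.comb(S, j) * (S - j) ** m
            total += -term if j % 2 else term
        return CoverageProbability(float(Fraction(total, S**m)), "exact")
    return _coverage_series(m, S)
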