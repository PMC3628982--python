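"""Independent brute-force oracles used by the test suite only."""

from fractions import Fraction
from math import comb


def hypergeom_weights(r1: int, r2: int, n1: int) -> tuple[int, list[int], int]:
    """Integer hypergeometric weights over all tables with fixed margins.

    For row sums ``r1``/``r2`` and first-column sum ``n1``, every table is
    determined by its top-left cell ``a``; the probability of each is
    ``comb(r1, a) * comb(r2, n1 - a) / comb(r1 + r2, n1)``.  Returns
    ``(lo, weights, denom)`` with ``weights[a - lo]`` the exact integer
    numerator of each feasible ``a``.
    """
    lo, hi = max(0, n1 - r2), min(r1, n1)
    weights = [comb(r1, a) * comb(r2, n1 - a) for a in range(lo, hi + 1)]
    return lo, weights, comb(r1 + r2, n1)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct enumeration of margin-fixed tables.

    Sums the exact (integer-arithmetic) hypergeometric probabilities of
    every table sharing the observed margins whose likelihood does not
    exceed the observed table's; ties at the observed likelihood are
    included with a 1e-7 relative tolerance, the standard convention for
    the two-sided minimum-likelihood test.
    """
    r1, r2, n1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or n1 == 0 or (b + d) == 0:
        return 1.0
    lo, weights, denom = hypergeom_weights(r1, r2, n1)
    w_obs = weights[a - lo]
    # w <= w_obs * (1 + 1e-7), kept in exact integers
    total = sum(w for w in weights if w * 10_000_000 <= w_obs * 10_000_001)
    return float(Fraction(total, denom))


def fisher_upper_tail_enumeration(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p: upper hypergeometric tail."""
    r1, r2, n1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or n1 == 0 or (b + d) == 0:
        return 1.0
    lo, weights, denom = hypergeom_weights(r1, r2, n1)
    return float(Fraction(sum(weights[a - lo :]), denom))


def bh_stepup_by_hand(p_values):
    """Benjamini–Hochberg step-up computed literally from its definition."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p_values[i] * m / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q
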