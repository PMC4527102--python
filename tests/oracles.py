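"""Independent oracles used to cross-check the implementation.

Each oracle recomputes a statistic by a different route than the library:
exact rational arithmetic, exhaustive enumeration, or arbitrary-precision
floating point.  None of them import from ``spcdiff.stats``.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import mpmath


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is at most the observed one (relative tie
    tolerance 1e-9).
    """
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k: int) -> Fraction:
        return Fraction(comb(c1, k) * comb(n - c1, r1 - k), comb(n, r1))

    p_obs = pmf(a)
    tol = 1 + Fraction(1, 10**9)
    total = sum(
        pmf(k)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        if pmf(k) <= p_obs * tol
    )
    return float(total)


def g_yates_mp(a: int, b: int, c: int, d: int, dps: int = 50) -> tuple[float, float]:
    """Yates-corrected G and its chi-square(1) upper-tail p at ``dps``
    decimal digits of precision (mpmath)."""
    with mpmath.workdps(dps):
        obs = [[mpmath.mpf(a), mpmath.mpf(b)], [mpmath.mpf(c), mpmath.mpf(d)]]
        rows = [obs[0][0] + obs[0][1], obs[1][0] + obs[1][1]]
        cols = [obs[0][0] + obs[1][0], obs[0][1] + obs[1][1]]
        total = rows[0] + rows[1]
        g = mpmath.mpf(0)
        for i in range(2):
            for j in range(2):
                e = rows[i] * cols[j] / total
                shift = e - obs[i][j]
                if shift > mpmath.mpf("0.5"):
                    shift = mpmath.mpf("0.5")
                elif shift < mpmath.mpf("-0.5"):
                    shift = mpmath.mpf("-0.5")
                o_adj = obs[i][j] + shift
                if o_adj > 0:
                    g += o_adj * mpmath.log(o_adj / e)
        g = 2 * g
        if g < 0:
            g = mpmath.mpf(0)
        # chi-square(1) survival function: erfc(sqrt(g/2))
        p = mpmath.erfc(mpmath.sqrt(g / 2))
        return float(g), float(p)


def mw_u_brute(control: list[float], case: list[float]) -> float:
    """U statistic (case wins, half credit for ties) by direct pair count."""
    u = 0.0
    for x in case:
        for y in control:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def all_tables_with_margins_leq(max_margin: int):
    """Yield every 2x2 table (a, b, c, d) of non-negative cells whose row
    and column sums are all in [1, max_margin]."""
    for r1 in range(1, max_margin + 1):
        for r2 in range(1, max_margin + 1):
            for a in range(r1 + 1):
                b = r1 - a
                for c in range(r2 + 1):
                    d = r2 - c
                    if 0 < a + c <= max_margin and 0 < b + d <= max_margin:
                        yield a, b, c, d
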