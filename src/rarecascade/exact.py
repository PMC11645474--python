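"""Exact small-sample tests used throughout the cascade.

Both the two-sided Fisher test and the exact Hardy-Weinberg test are
computed with integer (arbitrary-precision) point weights, so tie
comparisons between equally-likely tables are exact rather than subject to
a floating-point slack. The only floating-point step is the final division.
"""

from __future__ import annotations

import math
import warnings
from fractions import Fraction
from functools import lru_cache


class DegenerateTableWarning(UserWarning):
    pass


@lru_cache(maxsize=100_000)
def _fisher_margin_pvalues(r1: int, c1: int, n: int) -> dict[int, float]:
    """Two-sided p-value for every admissible cell a, at fixed margins.

    Margins: row1 total r1, column1 total c1, grand total n. The point
    probability of cell value x is C(r1,x)*C(n-r1,c1-x)/C(n,c1); integer
    numerator weights make the "no more probable than observed" comparison
    exact, ties included.
    """
    r2 = n - r1
    lo, hi = max(0, c1 - r2), min(r1, c1)
    xs = list(range(lo, hi + 1))
    weights = {x: math.comb(r1, x) * math.comb(r2, c1 - x) for x in xs}
    total = math.comb(n, c1)
    order = sorted(xs, key=weights.__getitem__)
    out: dict[int, float] = {}
    cum = 0
    i = 0
    while i < len(order):
        # advance over a tie-block of equal weights, then assign the shared p
        j = i
        block = 0
        while j < len(order) and weights[order[j]] == weights[order[i]]:
            block += weights[order[j]]
            j += 1
        cum += block
        p = float(Fraction(cum, total))
        for k in range(i, j):
            out[order[k]] = min(p, 1.0)
        i = j
    return out


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the observed
    margins whose point probability is <= that of the observed table.
    Degenerate margins (an empty row or column) give p = 1 with a warning.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    if n == 0 or a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        warnings.warn("degenerate 2x2 margins; p = 1", DegenerateTableWarning)
        return 1.0
    return _fisher_margin_pvalues(a + b, a + c, n)[a]


def odds_ratio(a: int, b: int, c: int, d: int, estimator: str = "haldane") -> float:
    """Odds ratio of the 2x2 table [[a, b], [c, d]].

    ``haldane``: cross-product (a*d)/(b*c); when any cell is zero, 0.5 is
    added to every cell (Haldane-Anscombe) so the estimate stays finite.
    ``cmle``: conditional maximum-likelihood estimate (may be 0 or inf on
    boundary tables).
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    if estimator == "haldane":
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)
    if estimator == "cmle":
        from scipy.stats.contingency import odds_ratio as _scipy_or

        return float(_scipy_or([[a, b], [c, d]], kind="conditional").statistic)
    raise ValueError(f"unknown estimator {estimator!r}")


def hwe_exact_p(n_aa_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value from genotype counts.

    Given the observed allele counts, enumerates every heterozygote count
    with the same allele margin; the p-value is the summed probability of
    all configurations no more probable than the observed one. Monomorphic
    sites have a single admissible configuration, hence p = 1.
    """
    if min(n_aa_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("no genotypes observed")
    n_a = 2 * n_aa_hom_major + n_het  # first-allele count
    n_b = 2 * n_hom_minor + n_het
    # weight(h) proportional to the probability of h heterozygotes at this
    # allele margin: 2^h * n! / (nAA! h! naa!)
    nf = math.factorial(n)

    def weight(h: int) -> int:
        return (
            (1 << h)
            * nf
            // (
                math.factorial((n_a - h) // 2)
                * math.factorial(h)
                * math.factorial((n_b - h) // 2)
            )
        )

    hs = [h for h in range(min(n_a, n_b) + 1) if (n_a - h) % 2 == 0 and (n_b - h) % 2 == 0]
    weights = {h: weight(h) for h in hs}
    w_obs = weights[n_het]
    num = sum(w for w in weights.values() if w <= w_obs)
    return min(float(Fraction(num, sum(weights.values()))), 1.0)
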