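"""Independent brute-force oracles for the exact tests.

These implement the test definitions directly from first principles with
exact rational arithmetic, as plainly as possible, and are kept free of any
code shared with the package implementations.
"""

from fractions import Fraction
from math import comb, factorial


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over tables with the
    observed margins, summing exact hypergeometric probabilities of every
    table no more probable than the observed one (ties included)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((x, Fraction(comb(r1, x) * comb(r2, c1 - x), denom)))
    obs = dict(probs)[a]
    return float(sum(q for _, q in probs if q <= obs))


def fisher_oracle_margin(r1: int, c1: int, n: int) -> dict[int, float]:
    """Oracle p for every admissible observed cell at fixed margins."""
    r2 = n - r1
    denom = comb(n, c1)
    probs = [
        (x, Fraction(comb(r1, x) * comb(r2, c1 - x), denom))
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
    ]
    return {
        x: float(sum(q for _, q in probs if q <= px)) for x, px in probs
    }


def hwe_oracle(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact Hardy-Weinberg p by enumerating every genotype-count triple
    compatible with the observed allele counts.

    The conditional probability of a triple (nAA, nAa, naa) given allele
    counts is proportional to the number of distinct ways to realise it:
    multinomial(n; nAA, nAa, naa) * 2**nAa.
    """
    n = n_hom_major + n_het + n_hom_minor
    n_a = 2 * n_hom_major + n_het
    n_b = 2 * n_hom_minor + n_het
    configs = []
    for haa in range(n + 1):
        for het in range(n - haa + 1):
            hbb = n - haa - het
            if 2 * haa + het == n_a and 2 * hbb + het == n_b:
                ways = (
                    Fraction(factorial(n), factorial(haa) * factorial(het) * factorial(hbb))
                    * 2**het
                )
                configs.append((het, ways))
    total = sum(w for _, w in configs)
    obs = dict(configs)[n_het]
    return float(sum(Fraction(w, total) for _, w in configs if w <= obs))
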