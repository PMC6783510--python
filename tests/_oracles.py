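"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity, not speed, and deliberately
avoids the code paths it is used to verify.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def naive_enrichment_score(
    genes: list[str],
    scores: list[float],
    members: set[str],
    exponent: float,
) -> tuple[float, int, list[float]]:
    """Materialise the weighted KS running sum step by step.

    Returns (es, 1-based peak index, full deviation trace). Pure-Python
    re-derivation from the definition: walk the ranked list, add
    |r|^p/N_R on a hit and 1/(N−N_H) on a miss, track the deviation of
    maximal magnitude (earliest position on ties).
    """
    n = len(genes)
    hits = [g in members for g in genes]
    n_h = sum(hits)
    n_r = sum(abs(s) ** exponent for s, h in zip(scores, hits) if h)
    p_hit = 0.0
    p_miss = 0.0
    best = 0.0
    best_pos = 0
    trace: list[float] = []
    for i, (s, h) in enumerate(zip(scores, hits), start=1):
        if h:
            p_hit += abs(s) ** exponent / n_r
        else:
            p_miss += 1.0 / (n - n_h)
        dev = p_hit - p_miss
        trace.append(dev)
        if abs(dev) > abs(best):
            best = dev
            best_pos = i
    return best, best_pos, trace


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full enumeration over fixed margins.

    Sums the hypergeometric point probabilities of every table no more
    probable than the observed one, in exact rational arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum((p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs), Fraction(0))
    return float(total)


def hypergeom_upper_tail(universe: int, term: int, query: int, overlap: int) -> float:
    """P[X ≥ overlap] for X ~ Hypergeom(universe, term, query), exact sum."""
    denom = comb(universe, query)
    hi = min(term, query)
    total = sum(
        Fraction(comb(term, x) * comb(universe - term, query - x), denom)
        for x in range(overlap, hi + 1)
    )
    return float(total)
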