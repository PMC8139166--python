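"""Shared overlap statistics: 2x2 tables, odds ratios, hypergeometric tails."""

from __future__ import annotations

from typing import Collection, Tuple

from scipy import stats


def overlap_table(
    set_a: Collection, set_b: Collection, universe: Collection
) -> Tuple[int, int, int, int]:
    """2x2 membership counts (a, b, c, d) of two sets over a universe.

    a = in both, b = A only, c = B only, d = neither; a+b+c+d = |universe|.
    Raises on empty universe or sets not contained in it.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    sa, sb = set(set_a), set(set_b)
    if not sa <= uni or not sb <= uni:
        raise ValueError("sets must be subsets of the universe")
    a = len(sa & sb)
    b = len(sa) - a
    c = len(sb) - a
    d = len(uni) - a - b - c
    return a, b, c, d


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a*d)/(b*c) with a Haldane-Anscombe 0.5 correction when any cell is 0."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def hypergeom_overlap_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided hypergeometric enrichment p, P(X >= a).

    X ~ Hypergeom(N=a+b+c+d, K=a+b, n=a+c): the overlap of a random set of
    size |B| with A over the universe.
    """
    n_universe = a + b + c + d
    return float(stats.hypergeom.sf(a - 1, n_universe, a + b, a + c))


def overlap_stats(set_a, set_b, universe):
    """Convenience: counts, odds ratio and one-sided enrichment p in one call."""
    a, b, c, d = overlap_table(set_a, set_b, universe)
    return {
        "a": a,
        "b": b,
        "c": c,
        "d": d,
        "odds_ratio": odds_ratio(a, b, c, d),
        "p": hypergeom_overlap_p(a, b, c, d),
    }


def cohens_d(x, y) -> float:
    """Cohen's d of mean(x) - mean(y) with pooled SD (n1+n2-2 denominator).

    Returns NaN when the pooled SD is zero or either group has < 2 values.
    """
    import numpy as np

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return float("nan")
    return float((x.mean() - y.mean()) / pooled_var**0.5)
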