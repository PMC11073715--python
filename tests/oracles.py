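"""Independent oracles used by the test suite.

Deliberately written with different machinery than the package itself:
exact rational enumeration for hypergeometric tails, direct pmf summation
for binomial tails, hand-coded step-up for BH, networkx shortest paths
for hop counts.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np


def fisher_right_oracle(a: int, b: int, c: int, d: int) -> float:
    """Right-tail Fisher p by exact rational summation over tables with
    the observed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    hi = min(r1, c1)
    denom = comb(n, c1)
    return float(sum(
        Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(a, hi + 1)
    ))


def fisher_left_oracle(a: int, b: int, c: int, d: int) -> float:
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo = max(0, r1 + c1 - n)
    denom = comb(n, c1)
    return float(sum(
        Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(lo, a + 1)
    ))


def fisher_two_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p: mass of all tables (fixed margins) whose exact
    rational probability is <= the observed table's."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    pmf = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    pa = pmf[a]
    return float(sum(v for v in pmf.values() if v <= pa))


def binom_upper_tail_oracle(x: int, n: int, p: float) -> float:
    """P[X >= x] for X ~ Binomial(n, p) by direct pmf summation.

    Terms are evaluated in log space so deep tails do not underflow."""
    import math

    if x <= 0:
        return 1.0
    if x > n or p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    log_terms = [
        math.log(comb(n, k)) + k * math.log(p) + (n - k) * math.log1p(-p)
        for k in range(x, n + 1)
    ]
    m = max(log_terms)
    total = math.exp(m) * sum(math.exp(t - m) for t in log_terms)
    return min(total, 1.0)


def bh_oracle(pvalues) -> np.ndarray:
    """Hand step-up: sort, multiply by m/rank, enforce monotonicity from
    the largest rank down, cap at 1, return in input order."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def hop_counts_oracle(edges, source, max_k):
    """Shortest hop counts via networkx (independent of the package BFS)."""
    g = nx.Graph()
    g.add_edges_from(edges)
    if source not in g:
        return {source: 0}
    lengths = nx.single_source_shortest_path_length(g, source, cutoff=max_k)
    return dict(lengths)


def spearman_oracle(x, y) -> float:
    """Spearman rho as Pearson correlation of midranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))
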