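"""Independent brute-force oracles used by the test suite only."""

from __future__ import annotations

import itertools
from fractions import Fraction

import numpy as np


def brute_force_permutation(series) -> tuple[int, int, Fraction]:
    """Naive sort-the-list paired permutation test.

    Enumerates every sign vector with itertools, computes each mean
    difference in exact rational arithmetic, sorts the list, and ranks the
    observed value.  Returns (rank_smallest, tie_count, raw midpoint p).
    Deliberately independent of the package implementation.
    """
    d = [
        Fraction(ma, na) - Fraction(mb, nb)
        for ma, na, mb, nb in zip(series.m_a, series.n_a, series.m_b, series.n_b)
    ]
    K = len(d)
    stats = []
    for signs in itertools.product((1, -1), repeat=K):
        stats.append(sum(s * x for s, x in zip(signs, d)) / K)
    obs = sum(d) / K
    stats.sort()
    rank = 1 + sum(1 for t in stats if t < obs)
    tie = sum(1 for t in stats if t == obs)
    total = len(stats)
    p = 1 - Fraction(2 * rank + tie, 2 * total)
    return rank, tie, p


def random_series(rng: np.random.Generator, max_k: int = 12):
    """A random rational paired cluster series with near-equal sizes."""
    from layerquant import PairedClusterSeries

    K = int(rng.integers(1, max_k + 1))
    base = int(rng.integers(1, 7))
    extra = int(rng.integers(0, K))

    def one_subject():
        sizes = [base + 1] * extra + [base] * (K - extra)
        m = [int(rng.integers(0, n + 1)) for n in sizes]
        return tuple(m), tuple(sizes)

    m_a, n_a = one_subject()
    m_b, n_b = one_subject()
    return PairedClusterSeries(m_a, n_a, m_b, n_b)


def manual_logrank(time, event, group) -> float:
    """Two-sample log-rank chi-square from first principles (risk tables)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)
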