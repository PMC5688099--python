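"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive
enumeration for the exact tests and the textbook Weir–Cockerham estimator
for Fst, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
from scipy.stats import rankdata


def enum_exclusivity_p(n: int, ka: int, kb: int, observed: int) -> float:
    """Exact P(co-occurrence <= observed) by enumerating every 2×2 table
    with margins (ka, kb) out of n, in exact rational arithmetic."""
    total = Fraction(0)
    for k in range(max(0, ka + kb - n), min(ka, kb) + 1):
        if k <= observed:
            total += Fraction(comb(ka, k) * comb(n - ka, kb - k), comb(n, kb))
    return float(total)


def enum_signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, dtype=float)
    assert (d != 0).all(), "zero differences must be dropped first"
    ranks = rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    dist: dict[float, int] = {}
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        dist[w] = dist.get(w, 0) + 1
    total = 2**n
    p_low = sum(c for w, c in dist.items() if w <= w_obs) / total
    p_high = sum(c for w, c in dist.items() if w >= w_obs) / total
    return min(1.0, 2 * min(p_low, p_high))


def weir_cockerham_fst(g1: np.ndarray, g2: np.ndarray) -> float:
    """Two-population Weir–Cockerham theta from 0/1/2 genotype vectors
    (variance-components a, b, c including heterozygosity terms)."""
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    n1, n2 = len(g1), len(g2)
    p1, p2 = g1.mean() / 2, g2.mean() / 2
    h1, h2 = (g1 == 1).mean(), (g2 == 1).mean()
    r = 2
    n_bar = (n1 + n2) / 2
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    den = a + b + c
    return float("nan") if den == 0 else float(a / den)


def hand_logrank_6subject() -> tuple[list, list, list, float]:
    """A 6-subject worked example with the log-rank statistic tabulated by
    hand over the pooled risk sets.

    Group 0: times 6 (event), 13 (event), 21 (censored);
    group 1: 8 (event), 10 (censored), 15 (event).
    Event-time table (n at risk, group-1 at risk, deaths):
      t=6:  n=6, n1=3, d=1 → E1 += 0.5,   V += 0.25
      t=8:  n=5, n1=3, d=1 → E1 += 0.6,   V += 0.24
      t=13: n=3, n1=1, d=1 → E1 += 1/3,   V += 2/9
      t=15: n=2, n1=1, d=1 → E1 += 0.5,   V += 0.25
    O1 = 2, so chi2 = (2 − 1.93333…)² / 0.962222… = 0.0046189…
    """
    times = [6, 13, 21, 8, 10, 15]
    events = [1, 1, 0, 1, 0, 1]
    group = [0, 0, 0, 1, 1, 1]
    e1 = 0.5 + 0.6 + 1 / 3 + 0.5
    v = 0.25 + 0.24 + 2 / 9 + 0.25
    stat = (2 - e1) ** 2 / v
    return times, events, group, stat
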