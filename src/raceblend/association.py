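"""Downstream association tests: pairwise mutual exclusivity, Kaplan–Meier
survival with the two-group log-rank test, and the paired Wilcoxon
signed-rank comparison.

Mutual exclusivity of two binary alteration profiles is tested exactly:
conditioning on both margins, the probability of observing at most the
observed co-occurrence count is the lower hypergeometric tail (a one-sided
Fisher-type test toward exclusivity). Survival comparisons are capped at
36 months by administrative censoring before estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "ExclusivityResult",
    "KMResult",
    "SignedRankResult",
    "exclusivity_test",
    "km_logrank",
    "paired_signed_rank",
]


@dataclass(frozen=True)
class ExclusivityResult:
    """One-sided exclusivity test for a feature pair.

    ``n_both / n_a_only / n_b_only / n_neither`` partition the evaluable
    samples; ``p_value`` is the fixed-margin probability of co-occurrence
    at most as large as observed. ``degenerate`` marks a zero margin.
    """

    n: int
    n_a: int
    n_b: int
    n_both: int
    p_value: float
    degenerate: bool = False

    @property
    def counts(self) -> dict:
        return {
            "both": self.n_both,
            "a_only": self.n_a - self.n_both,
            "b_only": self.n_b - self.n_both,
            "neither": self.n - self.n_a - self.n_b + self.n_both,
        }


@dataclass
class KMResult:
    curves: dict  # group label → DataFrame(time, n_risk, estimate)
    statistic: float
    p_value: float


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float
    p_value: float
    n_used: int
    degenerate: bool = False


def exclusivity_test(a, b) -> ExclusivityResult:
    """Exact one-sided test of mutual exclusivity between two 0/1 profiles.

    ``a`` and ``b`` must share a sample universe; pairs with a missing
    value (uncallable samples) are excluded first. With margins fixed, the
    p-value is ``P(X <= observed co-occurrences)`` for hypergeometric X —
    small p means the features co-occur less often than independence
    predicts. A zero margin makes the test degenerate (p = 1).
    """
    a = pd.Series(a).astype(float)
    b = pd.Series(b).astype(float)
    if len(a) != len(b):
        raise ValueError("profiles must have equal length")
    keep = a.notna().to_numpy() & b.notna().to_numpy()
    av = a.to_numpy()[keep].astype(int)
    bv = b.to_numpy()[keep].astype(int)
    n = int(keep.sum())
    n_a, n_b = int(av.sum()), int(bv.sum())
    n_both = int((av & bv).sum())
    if n_a == 0 or n_b == 0 or n_a == n or n_b == n:
        return ExclusivityResult(n, n_a, n_b, n_both, 1.0, degenerate=True)
    p = float(stats.hypergeom.cdf(n_both, n, n_a, n_b))
    return ExclusivityResult(n, n_a, n_b, n_both, p)


def km_logrank(times, events, group, cap_months: float = 36.0) -> KMResult:
    """Kaplan–Meier curves and two-group log-rank test, capped at 3 years.

    Observations beyond ``cap_months`` are administratively censored at
    the cap before estimation, so late events cannot drive the comparison.
    Each returned curve tabulates event times with the at-risk count and
    the product-limit estimate (starting at 1, non-increasing).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    if (times < 0).any():
        raise ValueError("negative survival times")
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    capped_e = np.where(times > cap_months, 0, events)
    capped_t = np.minimum(times, cap_months)
    curves = {}
    arms = {}
    for lab in labels:
        m = group == lab
        if m.sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        kmf = KaplanMeierFitter().fit(capped_t[m], capped_e[m], label=str(lab))
        table = kmf.event_table
        curves[lab] = pd.DataFrame(
            {
                "time": table.index.to_numpy(dtype=float),
                "n_risk": table["at_risk"].to_numpy(dtype=int),
                "n_events": table["observed"].to_numpy(dtype=int),
                "estimate": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
            }
        )
        arms[lab] = (capped_t[m], capped_e[m])
    (t0, e0), (t1, e1) = arms[labels[0]], arms[labels[1]]
    if capped_e.sum() == 0:
        return KMResult(curves=curves, statistic=0.0, p_value=1.0)
    res = logrank_test(t0, t1, event_observed_A=e0, event_observed_B=e1)
    return KMResult(curves=curves, statistic=float(res.test_statistic), p_value=float(res.p_value))


def paired_signed_rank(x, y) -> SignedRankResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped first. The null distribution is exact
    (sign enumeration) for up to 25 informative pairs and a normal
    approximation beyond. All-zero differences give a degenerate p of 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return SignedRankResult(statistic=0.0, p_value=1.0, n_used=0, degenerate=True)
    method = "exact" if n <= 25 else "approx"
    stat, p = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return SignedRankResult(statistic=float(stat), p_value=float(p), n_used=n)
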