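"""Biological-confounder removal: propensity scores, matching weights,
covariate balance, and the weighted chi-squared race-bias test.

The comparison of per-gene mutation frequencies between an Asian and a
Caucasian patient group is confounded by clinical covariates (age, gender,
stage, smoking, alcohol) whose distributions differ by group. The remedy:

1. fit a logistic regression of group membership on the covariates — the
   fitted probability is the propensity score *e*;
2. attach the matching weight ``min(e, 1−e) / P(own group)``, which
   emulates 1:1 pair matching by weighting;
3. declare the groups balanced when the standardized difference of the
   weighted propensity scores is below 10%;
4. compare weighted mutation frequencies gene by gene with a chi-squared
   statistic computed on the weighted 2×2 table rescaled to each group's
   Kish effective sample size ``n_eff = (Σw)² / Σw²``, then control the
   FDR with Benjamini–Hochberg and (optionally) validate the significant
   count against race-label permutations.

With unit weights the test reduces exactly to the classical Pearson
chi-squared, which anchors its correctness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SeparationError",
    "PropensityResult",
    "BalanceReport",
    "WeightedChisqResult",
    "PermutationResult",
    "DEFAULT_COVARIATES",
    "fit_propensity",
    "matching_weight",
    "standardized_difference",
    "check_balance",
    "weighted_chisq",
    "race_biased_genes",
    "permutation_significance",
]

DEFAULT_COVARIATES = ("age", "gender", "stage", "smoking", "alcohol")
#: Group whose membership probability the logistic model predicts.
TREATED_GROUP = "Asian"
REFERENCE_GROUP = "Caucasian"
SCORE_CLIP = 1e-6


class SeparationError(RuntimeError):
    """The logistic propensity fit is degenerate (complete separation)."""


@dataclass
class BalanceReport:
    """Standardized differences before/after weighting.

    ``table`` has one row per covariate level plus one for the propensity
    score itself; ``balanced`` is true iff the weighted propensity-score
    standardized difference is below the threshold.
    """

    table: pd.DataFrame
    score_std_diff_before: float
    score_std_diff_after: float
    threshold_pct: float
    balanced: bool


@dataclass(frozen=True)
class WeightedChisqResult:
    statistic: float
    p_value: float
    table: pd.DataFrame  # groups × {wildtype, mutated} on the n_eff scale


@dataclass
class PermutationResult:
    observed_significant: int
    permuted_counts: np.ndarray
    empirical_p: float
    n_resampled: int = 0


def _design_matrix(patients: pd.DataFrame, covariates) -> pd.DataFrame:
    """Indicator-code categoricals (age stays linear); drop single-level
    covariates with a warning."""
    parts = []
    for cov in covariates:
        if cov == "age":
            parts.append(patients["age"].astype(float).rename("age"))
            continue
        s = patients[cov].astype(str)
        if s.nunique() < 2:
            warnings.warn(f"covariate {cov!r} has a single level; dropped from the model")
            continue
        parts.append(pd.get_dummies(s, prefix=cov, drop_first=True, dtype=float))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=patients.index)
    return sm.add_constant(X, has_constant="add")


def matching_weight(score: np.ndarray, is_treated: np.ndarray) -> np.ndarray:
    """``min(e, 1−e)`` divided by the probability of the sample's own group."""
    score = np.asarray(score, dtype=float)
    own = np.where(is_treated, score, 1.0 - score)
    return np.minimum(score, 1.0 - score) / own


def fit_propensity(
    patients: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Maximum-likelihood logistic propensity fit with matching weights.

    Returns a table of ``sample_id, group, score, matching_weight`` where
    ``score`` is the fitted probability of Asian-group membership, clipped
    strictly inside (0, 1). Complete separation raises
    :class:`SeparationError` with a suggestion to reduce the covariates.
    """
    groups = set(patients["group"])
    if groups != {TREATED_GROUP, REFERENCE_GROUP}:
        raise ValueError(f"need exactly the groups {TREATED_GROUP}/{REFERENCE_GROUP}, got {sorted(groups)}")
    y = (patients["group"] == TREATED_GROUP).to_numpy(dtype=float)
    X = _design_matrix(patients, covariates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # quasi-separation produces benign convergence noise
        try:
            fit = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, method="lbfgs", maxiter=200)
            score = np.asarray(fit.predict(X.to_numpy(dtype=float)), dtype=float)
        except Exception as exc:  # statsmodels raises PerfectSeparationError on newton paths
            raise SeparationError(
                "propensity model failed to fit (likely separation); "
                "try fewer or coarser covariates"
            ) from exc
    if np.all(np.abs(score - y) < 1e-4):
        raise SeparationError(
            "complete separation: covariates perfectly predict the group; "
            "reduce the covariate set"
        )
    score = np.clip(score, SCORE_CLIP, 1.0 - SCORE_CLIP)
    is_treated = y.astype(bool)
    return pd.DataFrame(
        {
            "sample_id": patients["sample_id"].to_numpy(),
            "group": patients["group"].to_numpy(),
            "score": score,
            "matching_weight": matching_weight(score, is_treated),
        }
    )


def _wmean_wvar(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    m = float((w * x).sum() / sw)
    denom = sw - (w**2).sum() / sw  # reduces to n−1 at unit weights
    if denom <= 0:
        return m, 0.0
    v = float((w * (x - m) ** 2).sum() / denom)
    return m, v


def standardized_difference(
    x1, x2, w1=None, w2=None
) -> float:
    """Scale-free between-group difference in percent.

    ``100 × |m1 − m2| / sqrt((v1 + v2) / 2)`` with (weighted) means and
    variances. Zero pooled variance with unequal means is reported as
    infinity; with equal means as 0.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("need at least 2 samples per group")
    w1 = np.ones_like(x1) if w1 is None else np.asarray(w1, dtype=float)
    w2 = np.ones_like(x2) if w2 is None else np.asarray(w2, dtype=float)
    m1, v1 = _wmean_wvar(x1, w1)
    m2, v2 = _wmean_wvar(x2, w2)
    pooled = (v1 + v2) / 2.0
    diff = abs(m1 - m2)
    if pooled == 0:
        return 0.0 if diff == 0 else float("inf")
    return 100.0 * diff / np.sqrt(pooled)


def check_balance(
    patients: pd.DataFrame,
    propensity: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    threshold_pct: float = 10.0,
) -> BalanceReport:
    """Per-covariate and propensity-score balance diagnostics.

    Categorical covariates are assessed per indicator level. The
    ``balanced`` verdict follows the propensity-score criterion: weighted
    score standardized difference below ``threshold_pct``.
    """
    merged = patients.merge(propensity[["sample_id", "score", "matching_weight"]], on="sample_id")
    t = merged["group"] == TREATED_GROUP
    w = merged["matching_weight"].to_numpy()
    rows = []

    def add_row(name: str, level: str, values: np.ndarray) -> None:
        before = standardized_difference(values[t], values[~t])
        after = standardized_difference(values[t], values[~t], w[t.to_numpy()], w[(~t).to_numpy()])
        rows.append(
            {
                "covariate": name,
                "level": level,
                "std_diff_before_pct": before,
                "std_diff_after_pct": after,
            }
        )

    for cov in covariates:
        if cov == "age":
            add_row("age", "", merged["age"].to_numpy(dtype=float))
            continue
        for level in sorted(merged[cov].astype(str).unique()):
            add_row(cov, level, (merged[cov].astype(str) == level).to_numpy(dtype=float))
    score = merged["score"].to_numpy(dtype=float)
    score_before = standardized_difference(score[t], score[~t])
    score_after = standardized_difference(score[t], score[~t], w[t.to_numpy()], w[(~t).to_numpy()])
    rows.append(
        {
            "covariate": "propensity_score",
            "level": "",
            "std_diff_before_pct": score_before,
            "std_diff_after_pct": score_after,
        }
    )
    return BalanceReport(
        table=pd.DataFrame(rows),
        score_std_diff_before=score_before,
        score_std_diff_after=score_after,
        threshold_pct=threshold_pct,
        balanced=bool(score_after < threshold_pct),
    )


def _weighted_tests(
    M: np.ndarray, treated: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Vectorized weighted chi-squared over gene columns.

    Returns (freq_treated, freq_reference, statistic, p) plus the two
    effective sample sizes. The statistic is Pearson's on the 2×2 table of
    weighted mutation proportions rescaled to each group's effective
    sample size.
    """
    wt, wr = w[treated], w[~treated]
    swt, swr = wt.sum(), wr.sum()
    if swt <= 0 or swr <= 0:
        raise ValueError("a group has zero total weight")
    neff_t = swt**2 / (wt**2).sum()
    neff_r = swr**2 / (wr**2).sum()
    f_t = wt @ M[treated] / swt
    f_r = wr @ M[~treated] / swr
    a1, a0 = neff_t * f_t, neff_t * (1 - f_t)  # treated mutated / wildtype
    c1, c0 = neff_r * f_r, neff_r * (1 - f_r)
    n = neff_t + neff_r
    col1 = a1 + c1
    col0 = a0 + c0
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a1 * c0 - a0 * c1) ** 2 / (neff_t * neff_r * col1 * col0)
    stat = np.where((col1 <= 0) | (col0 <= 0), 0.0, stat)
    p = stats.chi2.sf(stat, df=1)
    p = np.where(stat == 0.0, 1.0, p)
    return f_t, f_r, stat, p, neff_t, neff_r


def weighted_chisq(mutated, group, weights) -> WeightedChisqResult:
    """Weighted chi-squared test of mutation frequency between two groups.

    With all weights 1 this reproduces the classical (uncorrected) Pearson
    chi-squared on the raw 2×2 table. Degenerate tables (all mutated or
    all wildtype) give statistic 0 and p 1.
    """
    mutated = np.asarray(mutated, dtype=float).reshape(-1, 1)
    group = np.asarray(group)
    w = np.asarray(weights, dtype=float)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    treated_label = TREATED_GROUP if TREATED_GROUP in labels else labels[0]
    treated = group == treated_label
    f_t, f_r, stat, p, neff_t, neff_r = _weighted_tests(mutated, treated, w)
    other = [l for l in labels if l != treated_label][0]
    table = pd.DataFrame(
        {
            "wildtype": [neff_t * (1 - f_t[0]), neff_r * (1 - f_r[0])],
            "mutated": [neff_t * f_t[0], neff_r * f_r[0]],
        },
        index=pd.Index([treated_label, other], name="group"),
    )
    return WeightedChisqResult(statistic=float(stat[0]), p_value=float(p[0]), table=table)


def race_biased_genes(
    matrix: pd.DataFrame,
    patients: pd.DataFrame,
    propensity: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
    min_freq: float = 0.05,
    fdr_threshold: float = 0.1,
    require_balance: bool = True,
) -> pd.DataFrame:
    """Per-gene weighted chi-squared scan with Benjamini–Hochberg FDR.

    Genes whose weighted mutation frequency reaches ``min_freq`` in at
    least one group are tested; results are sorted by FDR then statistic.
    ``direction`` labels which group has the higher weighted frequency.
    If the balance check fails the scan proceeds but warns (and the report
    carries ``balanced=False`` in ``attrs``).
    """
    if propensity is None:
        propensity = fit_propensity(patients, covariates)
    merged = patients[["sample_id", "group"]].merge(propensity, on=["sample_id", "group"])
    aligned = matrix.reindex(merged["sample_id"])
    if aligned.isna().any().any():
        missing = aligned.index[aligned.isna().any(axis=1)][:3].tolist()
        raise ValueError(f"mutation matrix lacks rows for samples {missing}")
    balanced = True
    if require_balance:
        report = check_balance(patients, propensity, covariates)
        balanced = report.balanced
        if not balanced:
            warnings.warn(
                "weighted propensity scores are not balanced "
                f"({report.score_std_diff_after:.1f}% >= {report.threshold_pct}%); "
                "proceeding, interpret with caution"
            )
    treated = (merged["group"] == TREATED_GROUP).to_numpy()
    w = merged["matching_weight"].to_numpy(dtype=float)
    M = aligned.to_numpy(dtype=float)
    f_t, f_r, stat, p, neff_t, neff_r = _weighted_tests(M, treated, w)
    keep = np.maximum(f_t, f_r) >= min_freq
    if not keep.any():
        warnings.warn("no gene passes the frequency filter; empty result")
        out = pd.DataFrame(
            columns=[
                "gene", "freq_asian", "freq_caucasian", "n_eff_asian", "n_eff_caucasian",
                "statistic", "p_value", "fdr", "direction", "significant",
            ]
        )
        out.attrs["balanced"] = balanced
        return out
    genes = np.asarray(matrix.columns)[keep]
    p_kept = p[keep]
    fdr = multipletests(p_kept, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": genes,
            "freq_asian": f_t[keep],
            "freq_caucasian": f_r[keep],
            "n_eff_asian": neff_t,
            "n_eff_caucasian": neff_r,
            "statistic": stat[keep],
            "p_value": p_kept,
            "fdr": fdr,
            "direction": np.where(f_t[keep] >= f_r[keep], "asian_higher", "caucasian_higher"),
        }
    )
    out["significant"] = out["fdr"] <= fdr_threshold
    out = out.sort_values(["fdr", "statistic"], ascending=[True, False], kind="stable").reset_index(drop=True)
    out.attrs["balanced"] = balanced
    return out


def permutation_significance(
    matrix: pd.DataFrame,
    patients: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    n_perm: int = 100,
    seed: int = 0,
    min_freq: float = 0.05,
    fdr_threshold: float = 0.1,
) -> PermutationResult:
    """Race-label permutation check of the significant-gene count.

    Each permutation shuffles the group labels, refits the propensity
    model from scratch, and reruns the whole gene scan; the empirical p is
    ``(1 + #{permuted ≥ observed}) / (n_perm + 1)``. Permutations whose
    propensity fit separates are resampled (and counted).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = int(
        race_biased_genes(
            matrix, patients, covariates=covariates, min_freq=min_freq,
            fdr_threshold=fdr_threshold, require_balance=False,
        )["significant"].sum()
    )
    rng = np.random.default_rng(seed)
    counts = []
    n_resampled = 0
    attempts_left = 20 * n_perm
    while len(counts) < n_perm:
        if attempts_left <= 0:
            raise SeparationError("too many permutations failed with separation")
        attempts_left -= 1
        shuffled = patients.copy()
        shuffled["group"] = rng.permutation(shuffled["group"].to_numpy())
        try:
            res = race_biased_genes(
                matrix, shuffled, covariates=covariates, min_freq=min_freq,
                fdr_threshold=fdr_threshold, require_balance=False,
            )
        except SeparationError:
            n_resampled += 1
            continue
        counts.append(int(res["significant"].sum()))
    counts = np.asarray(counts)
    empirical_p = (1 + int((counts >= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed_significant=observed,
        permuted_counts=counts,
        empirical_p=empirical_p,
        n_resampled=n_resampled,
    )
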