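"""Technical-confounder removal: caller merging, panel-of-normals
filtering, per-exon depth downsampling with consensus re-calling, and the
targeted-sequencing validation rate.

Sequencing depth differs systematically between cohorts, which inflates
the apparent mutation burden of the deeper cohort. The remedy is binomial
thinning of per-site read counts so that every exon reaches a similar mean
depth across cohorts (standardized difference below 10%), repeated over
independent iterations; only consensus calls (made in at least 8 of 10
iterations) survive. Thinning acts on counts, not reads — statistically
equivalent for calling decisions made on counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import MutationRecord

__all__ = [
    "CallerParams",
    "ConsensusResult",
    "ValidationRate",
    "merge_callers",
    "filter_germline_panel",
    "exon_depth_summary",
    "compute_downsampling_fractions",
    "depth_balance_report",
    "thin_counts",
    "call_sites",
    "call_site",
    "consensus_calls",
    "validation_rate",
]

SITE_COLS = ["sample_id", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds of the count-based somatic caller.

    The caller stands in for an external multi-caller ensemble: a site is
    called iff ``t_alt >= min_alt_reads``, VAF ``>= min_vaf``, tumor depth
    ``>= min_depth``, and the matched normal shows an alt fraction below
    ``max_normal_vaf``. ``strand_bias_filter`` is accepted for interface
    completeness but is a documented no-op: the count model carries no
    strand information.
    """

    min_alt_reads: int = 4
    min_vaf: float = 0.05
    min_depth: int = 10
    max_normal_vaf: float = 0.05
    strand_bias_filter: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.min_vaf <= 1.0:
            raise ValueError(f"min_vaf must be in (0, 1], got {self.min_vaf}")
        if self.min_alt_reads < 0 or self.min_depth < 0:
            raise ValueError("count thresholds must be >= 0")


@dataclass(frozen=True)
class ConsensusResult:
    """Per-site consensus outcome over downsampling iterations."""

    site_key: tuple
    times_called: int
    consensus: bool


@dataclass(frozen=True)
class ValidationRate:
    n_assessed: int
    n_confirmed: int
    rate_percent: float


def merge_callers(
    records: Sequence[MutationRecord], min_callers: int = 2
) -> list[MutationRecord]:
    """Keep records reported by at least ``min_callers`` callers."""
    for r in records:
        if not r.callers:
            raise ValueError(
                f"record {r.sample_id} {r.chrom}:{r.pos} has an empty caller set"
            )
    return [r for r in records if len(r.callers) >= min_callers]


def filter_germline_panel(
    records: Sequence[MutationRecord],
    normal_calls: pd.DataFrame,
    max_normals: int = 1,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Panel-of-normals filter: drop sites seen in more than ``max_normals``
    normal samples.

    ``normal_calls`` is a long table of per-normal variant sites with
    columns ``sample_id, chrom, pos, ref, alt``. A site present in exactly
    ``max_normals`` normals is kept (the removal criterion is strictly
    "more than"). Returns the kept records and a removal log.
    """
    if len(normal_calls) == 0:
        return list(records), pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "n_normals"])
    counts = (
        normal_calls.drop_duplicates(subset=SITE_COLS)
        .groupby(["chrom", "pos", "ref", "alt"])
        .size()
        .rename("n_normals")
        .reset_index()
    )
    flagged = counts[counts["n_normals"] > max_normals]
    bad = set(map(tuple, flagged[["chrom", "pos", "ref", "alt"]].itertuples(index=False)))
    kept = [r for r in records if (r.chrom, r.pos, r.ref, r.alt) not in bad]
    return kept, flagged.reset_index(drop=True)


def exon_depth_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-exon per-cohort tumor depth: mean, variance, sample count."""
    df = counts.copy()
    df["depth"] = df["t_ref"] + df["t_alt"]
    out = (
        df.groupby(["exon_id", "cohort"])["depth"]
        .agg(mean_depth="mean", var_depth="var", n="size")
        .reset_index()
    )
    return out


def compute_downsampling_fractions(depths: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-cohort per-exon thinning fractions targeting the minimum depth.

    ``depths`` needs columns ``exon_id, cohort, mean_depth``. For each exon
    the target is the minimum cohort mean, so the cohort already at the
    minimum gets fraction 1 and the others ``target / mean``; the expected
    thinned means then agree exactly, which drives the pairwise
    standardized depth difference below the 10% balance criterion. Exons
    absent in at least one cohort are excluded and returned as flags.
    """
    if (depths["mean_depth"] <= 0).any():
        bad = depths.loc[depths["mean_depth"] <= 0, "exon_id"].iloc[0]
        raise ValueError(f"non-positive mean depth for exon {bad!r}")
    n_cohorts = depths["cohort"].nunique()
    counts = depths.groupby("exon_id")["cohort"].nunique()
    excluded = sorted(counts.index[counts < n_cohorts])
    usable = depths[~depths["exon_id"].isin(excluded)].copy()
    target = usable.groupby("exon_id")["mean_depth"].transform("min")
    usable["fraction"] = np.minimum(1.0, target / usable["mean_depth"])
    return usable[["exon_id", "cohort", "fraction"]].reset_index(drop=True), excluded


def depth_balance_report(counts: pd.DataFrame) -> pd.DataFrame:
    """Pairwise per-exon standardized depth differences between cohorts.

    Standardized difference (pooled-variance form):
    ``100 × |m1 − m2| / sqrt((v1 + v2) / 2)``, computed from per-sample
    tumor depths within each cohort at each exon.
    """
    summary = exon_depth_summary(counts)
    rows = []
    for exon, sub in summary.groupby("exon_id"):
        sub = sub.reset_index(drop=True)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                v = (sub.loc[i, "var_depth"] + sub.loc[j, "var_depth"]) / 2.0
                diff = abs(sub.loc[i, "mean_depth"] - sub.loc[j, "mean_depth"])
                std_diff = 0.0 if diff == 0 else (np.inf if v == 0 else 100.0 * diff / np.sqrt(v))
                rows.append(
                    {
                        "exon_id": exon,
                        "cohort_a": sub.loc[i, "cohort"],
                        "cohort_b": sub.loc[j, "cohort"],
                        "std_diff_percent": std_diff,
                    }
                )
    return pd.DataFrame(rows)


def thin_counts(counts: pd.DataFrame, fractions: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Binomially thin tumor read counts per site.

    Each of ``t_ref`` and ``t_alt`` is independently thinned with the
    site's (cohort, exon) fraction; rows without a fraction (flagged exons)
    keep fraction 1. Thinning can only decrease counts, and fraction 1 is
    an exact identity.
    """
    frac = counts.merge(fractions, on=["exon_id", "cohort"], how="left")["fraction"].fillna(1.0)
    if ((frac <= 0) | (frac > 1)).any():
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out = counts.copy()
    f = frac.to_numpy()
    needs = f < 1.0
    for col in ("t_ref", "t_alt"):
        vals = out[col].to_numpy().copy()
        vals[needs] = rng.binomial(vals[needs], f[needs])
        out[col] = vals
    return out


def call_sites(counts: pd.DataFrame, params: CallerParams) -> pd.Series:
    """Vectorized caller: boolean per row of ``counts``.

    Zero tumor depth is never called (no division error); normal depth 0
    is treated as a clean normal.
    """
    t_alt = counts["t_alt"].to_numpy(dtype=float)
    depth = t_alt + counts["t_ref"].to_numpy(dtype=float)
    vaf = np.divide(t_alt, depth, out=np.zeros_like(t_alt), where=depth > 0)
    ok = (t_alt >= params.min_alt_reads) & (depth >= params.min_depth) & (vaf >= params.min_vaf)
    if "n_alt" in counts.columns:
        n_alt = counts["n_alt"].to_numpy(dtype=float)
        n_depth = n_alt + counts["n_ref"].to_numpy(dtype=float)
        n_vaf = np.divide(n_alt, n_depth, out=np.zeros_like(n_alt), where=n_depth > 0)
        ok &= n_vaf < params.max_normal_vaf
    return pd.Series(ok, index=counts.index, name="called")


def call_site(
    t_ref: int, t_alt: int, n_ref: int = 0, n_alt: int = 0, params: CallerParams | None = None
) -> bool:
    """Single-site convenience wrapper around :func:`call_sites`."""
    params = params or CallerParams()
    row = pd.DataFrame(
        {"t_ref": [t_ref], "t_alt": [t_alt], "n_ref": [n_ref], "n_alt": [n_alt]}
    )
    return bool(call_sites(row, params).iloc[0])


def consensus_calls(
    counts: pd.DataFrame,
    fractions: pd.DataFrame,
    params: CallerParams,
    n_iterations: int = 10,
    min_times: int = 8,
    base_seed: int = 0,
    seeds: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Repeat thin → call over independent iterations; keep consensus sites.

    Iteration *i* uses seed ``base_seed + i`` unless explicit ``seeds`` are
    given (duplicates are an error). Returns one row per site that was
    called at least once, with ``times_called`` and the consensus flag
    (called in at least ``min_times`` iterations).
    """
    if seeds is None:
        seeds = [base_seed + i for i in range(n_iterations)]
    seeds = list(seeds)
    if len(seeds) != n_iterations:
        raise ValueError(f"need {n_iterations} seeds, got {len(seeds)}")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds across iterations")
    if n_iterations < min_times:
        raise ValueError("n_iterations must be >= min_times")
    times = np.zeros(len(counts), dtype=int)
    for s in seeds:
        thinned = thin_counts(counts, fractions, seed=s)
        times += call_sites(thinned, params).to_numpy()
    out = counts[SITE_COLS + [c for c in ("cohort", "gene", "exon_id") if c in counts.columns]].copy()
    out["times_called"] = times
    out = out[out["times_called"] > 0].reset_index(drop=True)
    out["consensus"] = out["times_called"] >= min_times
    return out


def validation_rate(
    wes_calls: pd.DataFrame,
    targeted: pd.DataFrame,
    min_targeted_depth: int = 200,
) -> ValidationRate:
    """True-positive validation rate of WES calls against targeted resequencing.

    ``wes_calls`` carries site keys (``sample_id, chrom, pos, ref, alt``);
    ``targeted`` the same keys plus ``depth`` and a boolean ``called``.
    Assessed = WES calls whose site has targeted depth >= the threshold;
    confirmed = assessed sites also called in the targeted data. The rate
    is reported in percent to one decimal. Zero assessable sites leave the
    rate undefined and raise.
    """
    merged = wes_calls[SITE_COLS].merge(
        targeted[SITE_COLS + ["depth", "called"]], on=SITE_COLS, how="left"
    )
    assessable = merged[merged["depth"].fillna(0) >= min_targeted_depth]
    n_assessed = len(assessable)
    if n_assessed == 0:
        raise ValueError("no WES call reaches the targeted depth threshold; rate undefined")
    n_confirmed = int(assessable["called"].fillna(False).sum())
    rate = round(100.0 * n_confirmed / n_assessed, 1)
    return ValidationRate(n_assessed=n_assessed, n_confirmed=n_confirmed, rate_percent=rate)
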