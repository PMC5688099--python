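"""Germline-side computations: Hudson Fst, genotype coding and filtering,
hierarchical sample clustering, and SNP-status inference from sparse read
support.

The fixation index quantifies allele-frequency differentiation between
two populations (0 = identical frequencies, 1 = fixed difference). The
Hudson two-population estimator is used: unbiased in the sample
frequencies, frequency-based (no genotype-level terms), appropriate for a
comparison between population panels. Negative raw estimates are clipped
to 0 for reporting; the raw value is retained for auditability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "FstRecord",
    "SnpStatusCall",
    "ClusterResult",
    "hudson_fst",
    "fst_scan",
    "snp_filter_and_code",
    "cluster_samples",
    "infer_snp_status",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class FstRecord:
    snp_id: str | None
    p1: float
    p2: float
    n1: int
    n2: int
    fst_raw: float
    fst: float  # clipped to [0, 1]


@dataclass(frozen=True)
class SnpStatusCall:
    sample_id: str
    snp_id: str
    status: str  # carrier / non-carrier / uncallable
    supporting_reads: int


@dataclass
class ClusterResult:
    labels: pd.Series  # sample_id → cluster id (1-based)
    linkage: np.ndarray
    newick: str
    crosstab: pd.DataFrame | None = None


def hudson_fst(p1: float, n1: int, p2: float, n2: int, snp_id: str | None = None) -> FstRecord:
    """Hudson's two-population Fst estimator from allele frequencies.

    Numerator ``(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)`` (the
    sampling-correction terms remove the within-population noise),
    denominator ``p1(1−p2) + p2(1−p1)``. ``n1, n2`` are allele counts
    (2 × diploid samples); a zero denominator defines Fst as 0.
    """
    if n1 <= 1 or n2 <= 1:
        raise ValueError(f"allele counts must be >= 2, got n1={n1}, n2={n2}")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    raw = 0.0 if den == 0 else num / den
    return FstRecord(
        snp_id=snp_id, p1=float(p1), p2=float(p2), n1=int(n1), n2=int(n2),
        fst_raw=float(raw), fst=float(np.clip(raw, 0.0, 1.0)),
    )


def fst_scan(
    genotypes: pd.DataFrame,
    groups: pd.Series,
    pop1: str = "Asian",
    pop2: str = "Caucasian",
) -> pd.DataFrame:
    """Per-SNP Hudson Fst between two groups from a 0/1/2 genotype matrix.

    Allele frequencies and counts are computed over non-missing genotypes;
    SNPs with fewer than 2 alleles in either group are skipped.
    """
    groups = groups.reindex(genotypes.index)
    rows = []
    g1 = genotypes[groups == pop1]
    g2 = genotypes[groups == pop2]
    for snp in genotypes.columns:
        v1 = g1[snp].dropna().to_numpy(dtype=float)
        v2 = g2[snp].dropna().to_numpy(dtype=float)
        n1, n2 = 2 * len(v1), 2 * len(v2)
        if n1 <= 1 or n2 <= 1:
            continue
        p1 = v1.sum() / n1
        p2 = v2.sum() / n2
        rec = hudson_fst(p1, n1, p2, n2, snp_id=snp)
        rows.append(
            {"snp_id": snp, "p1": rec.p1, "p2": rec.p2, "n1": n1, "n2": n2,
             "fst_raw": rec.fst_raw, "fst": rec.fst}
        )
    return pd.DataFrame(rows).sort_values("fst", ascending=False, kind="stable").reset_index(drop=True)


def snp_filter_and_code(
    coverage_table: pd.DataFrame,
    min_coverage: int = 8,
    min_base_quality: int = 15,
) -> pd.DataFrame:
    """Code genotypes 0/1/2 and keep only SNPs covered in every sample.

    ``coverage_table`` is long, with columns ``sample_id, snp_id,
    coverage, genotype`` and optionally ``base_quality`` (rows below the
    quality floor are treated as uncovered). A SNP is retained only if its
    coverage is at least ``min_coverage`` in *every* sample.
    """
    df = coverage_table.copy()
    if "base_quality" in df.columns:
        df = df[df["base_quality"] >= min_base_quality]
    bad = set(df["genotype"].dropna().unique()) - {0, 1, 2}
    if bad:
        raise ValueError(f"genotypes must be coded 0/1/2, found {sorted(bad)}")
    samples = coverage_table["sample_id"].unique()
    covered = df[df["coverage"] >= min_coverage]
    per_snp = covered.groupby("snp_id")["sample_id"].nunique()
    keep = set(per_snp.index[per_snp == len(samples)])
    wide = (
        covered[covered["snp_id"].isin(keep)]
        .pivot(index="sample_id", columns="snp_id", values="genotype")
        .reindex(samples)
    )
    wide.index.name = "sample_id"
    wide.columns.name = None
    return wide.astype("Float64")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


def cluster_samples(
    genotypes: pd.DataFrame,
    n_clusters: int = 2,
    metric: str = "euclidean",
    method: str = "average",
    max_missing_frac: float = 0.05,
    cohorts: pd.Series | None = None,
) -> ClusterResult:
    """Agglomerative clustering of samples on 0/1/2 genotype codes.

    Missing genotypes beyond ``max_missing_frac`` overall are an error;
    below it they are imputed with the SNP mean. The tree is cut at
    ``n_clusters``; if cohort labels are supplied a cluster × cohort
    cross-tabulation is attached.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = genotypes.to_numpy(dtype=float)
    missing = np.isnan(X)
    if missing.all(axis=1).any():
        raise ValueError("a sample has no called genotypes")
    frac = missing.mean()
    if frac > max_missing_frac:
        raise ValueError(
            f"missing genotype fraction {frac:.3f} exceeds the allowed {max_missing_frac}"
        )
    if missing.any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(missing, col_means[None, :], X)
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    assignment = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series(assignment, index=genotypes.index, name="cluster")
    crosstab = None
    if cohorts is not None:
        crosstab = pd.crosstab(labels, cohorts.reindex(genotypes.index))
    return ClusterResult(
        labels=labels,
        linkage=Z,
        newick=linkage_to_newick(Z, list(genotypes.index.astype(str))),
        crosstab=crosstab,
    )


def infer_snp_status(
    reads: pd.DataFrame,
    min_reads: int = 3,
    min_alt_reads: int = 1,
) -> pd.DataFrame:
    """Call carrier status from (off-target) read support at a SNP site.

    ``reads`` has columns ``sample_id, snp_id, ref_reads, alt_reads``.
    Total coverage below ``min_reads`` is uncallable; otherwise a sample
    is a carrier iff it shows at least ``min_alt_reads`` alternate reads —
    deliberately lenient, matching inference from sparse off-target
    coverage.
    """
    cov = reads["ref_reads"].to_numpy() + reads["alt_reads"].to_numpy()
    alt = reads["alt_reads"].to_numpy()
    status = np.where(
        cov < min_reads, "uncallable", np.where(alt >= min_alt_reads, "carrier", "non-carrier")
    )
    out = reads[["sample_id", "snp_id"]].copy()
    out["status"] = status
    out["supporting_reads"] = np.where(status == "carrier", alt, cov)
    return out
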