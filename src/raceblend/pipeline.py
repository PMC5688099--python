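"""End-to-end orchestration: simulate → harmonize → compare → popgen →
associate, with a manifest that makes every output reproducible.

Each stage writes its tables under the run directory; a failure aborts
with the stage name while earlier artifacts remain on disk. The manifest
records the configuration, seeds, thresholds, library versions and
per-stage record counts (an auditable filter ledger).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import exclusivity_test, km_logrank, paired_signed_rank
from .balance import check_balance, fit_propensity, permutation_significance, race_biased_genes
from .harmonize import (
    CallerParams,
    SITE_COLS,
    compute_downsampling_fractions,
    consensus_calls,
    depth_balance_report,
    exon_depth_summary,
    filter_germline_panel,
    merge_callers,
    thin_counts,
)
from .io import build_mutation_matrix, write_clinical, write_genotypes
from .popgen import cluster_samples, fst_scan
from .synthetic import Scenario, default_scenario

logger = logging.getLogger("raceblend")

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage, artifacts are preserved."""


@dataclass
class RunConfig:
    """All thresholds of the analysis plus the scenario and base seed."""

    scenario: Scenario = field(default_factory=default_scenario)
    seed: int = 0
    min_callers: int = 2
    max_normals: int = 1
    n_iterations: int = 10
    min_times: int = 8
    depth_balance_threshold_pct: float = 10.0
    min_alt_reads: int = 4
    min_vaf: float = 0.05
    min_depth: int = 10
    fdr_threshold: float = 0.1
    min_freq: float = 0.05
    n_perm: int = 100
    survival_cap_months: float = 36.0
    snp_min_reads: int = 3
    snp_min_coverage: int = 8
    min_base_quality: int = 15

    def __post_init__(self) -> None:
        if self.n_iterations < self.min_times:
            raise ValueError("n_iterations must be >= min_times")
        if not 0 <= self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in [0, 1]")
        if self.n_perm < 0:
            raise ValueError("n_perm must be >= 0")

    def caller_params(self) -> CallerParams:
        return CallerParams(
            min_alt_reads=self.min_alt_reads, min_vaf=self.min_vaf, min_depth=self.min_depth
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scenario"] = self.scenario.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["scenario"] = Scenario.from_dict(d["scenario"])
        return cls(**d)


@dataclass
class PipelineResult:
    outdir: Path
    summary: dict
    gene_tests: pd.DataFrame
    balance_table: pd.DataFrame
    consensus: pd.DataFrame
    fst: pd.DataFrame | None


def _normal_variant_sites(readcounts: pd.DataFrame) -> pd.DataFrame:
    """Sites with germline-grade evidence in a normal sample (alt fraction
    >= 0.2 with >= 3 alt reads)."""
    n_depth = readcounts["n_ref"] + readcounts["n_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        n_vaf = np.where(n_depth > 0, readcounts["n_alt"] / n_depth, 0.0)
    hits = readcounts[(readcounts["n_alt"] >= 3) & (n_vaf >= 0.2)]
    return hits[SITE_COLS].copy()


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Run the full comparison on a synthetic scenario.

    Writes every intermediate table under ``outdir`` plus ``manifest.yaml``
    and ``summary.json``; re-running with the same config yields byte-
    identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    ledger: dict = {}
    stage = "simulate"
    try:
        data = config.scenario.generate(config.seed)
        paths = data.write(outdir / "inputs")
        patients = data.clinical
        ledger["simulate"] = {
            "n_samples": len(patients),
            "n_genes": data.matrix.shape[1],
            "n_readcount_rows": len(data.readcounts),
        }
        logger.info("simulate: %d samples, %d genes", len(patients), data.matrix.shape[1])

        stage = "harmonize"
        records = data.mutation_records()
        merged = merge_callers(records, config.min_callers)
        normal_calls = _normal_variant_sites(data.readcounts)
        filtered, removed = filter_germline_panel(merged, normal_calls, config.max_normals)
        ledger["harmonize"] = {
            "records_in": len(records),
            "after_caller_merge": len(merged),
            "after_normal_panel": len(filtered),
            "panel_sites_removed": len(removed),
        }
        keys = {r.site_key() for r in filtered}
        counts = data.readcounts
        candidate = counts[[tuple(t) in keys for t in counts[SITE_COLS].itertuples(index=False)]]
        depths = exon_depth_summary(counts)
        fractions, excluded_exons = compute_downsampling_fractions(depths)
        params = config.caller_params()
        before = consensus_calls(
            candidate, fractions.assign(fraction=1.0), params,
            config.n_iterations, config.min_times, base_seed=config.seed + 1_000,
        )
        after = consensus_calls(
            candidate, fractions, params,
            config.n_iterations, config.min_times, base_seed=config.seed + 2_000,
        )
        thinned_example = thin_counts(counts, fractions, seed=config.seed + 3_000)
        balance_after = depth_balance_report(thinned_example)
        fractions.to_csv(outdir / "downsampling_fractions.tsv", sep="\t", index=False)
        after.to_csv(outdir / "consensus_calls.tsv", sep="\t", index=False)
        balance_after.to_csv(outdir / "depth_balance.tsv", sep="\t", index=False)
        per_cohort = {}
        for label, cons in (("before", before), ("after", after)):
            counts_by = cons[cons["consensus"]].groupby("cohort").size()
            per_cohort[label] = counts_by.to_dict()
        reductions = {
            c: 1.0 - per_cohort["after"].get(c, 0) / per_cohort["before"].get(c, 1)
            for c in per_cohort["before"]
        }
        summary["consensus_counts"] = per_cohort
        summary["consensus_reduction_fraction"] = reductions
        summary["max_depth_std_diff_pct"] = float(balance_after["std_diff_percent"].max())
        summary["excluded_exons"] = excluded_exons
        consensus_sites = {
            tuple(t)
            for t in after[after["consensus"]][SITE_COLS].itertuples(index=False)
        }
        final_records = [r for r in filtered if r.site_key() in consensus_sites]
        matrix = build_mutation_matrix(final_records, patients, non_silent_only=True)
        matrix.to_csv(outdir / "mutation_matrix.tsv", sep="\t")
        ledger["harmonize"]["consensus_records"] = len(final_records)

        stage = "compare"
        propensity = fit_propensity(patients)
        balance = check_balance(patients, propensity, threshold_pct=config.depth_balance_threshold_pct)
        gene_tests = race_biased_genes(
            matrix, patients, propensity,
            min_freq=config.min_freq, fdr_threshold=config.fdr_threshold,
        )
        propensity.to_csv(outdir / "propensity.tsv", sep="\t", index=False)
        balance.table.to_csv(outdir / "balance.tsv", sep="\t", index=False)
        gene_tests.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)
        summary["balanced"] = balance.balanced
        summary["score_std_diff_after_pct"] = balance.score_std_diff_after
        summary["n_significant_genes"] = int(gene_tests["significant"].sum())
        summary["significant_genes"] = gene_tests.loc[gene_tests["significant"], "gene"].tolist()
        if config.n_perm > 0:
            perm = permutation_significance(
                matrix, patients, n_perm=config.n_perm, seed=config.seed + 4_000,
                min_freq=config.min_freq, fdr_threshold=config.fdr_threshold,
            )
            (outdir / "permutation.json").write_text(
                json.dumps(
                    {
                        "observed_significant": perm.observed_significant,
                        "permuted_counts": perm.permuted_counts.tolist(),
                        "empirical_p": perm.empirical_p,
                        "n_resampled": perm.n_resampled,
                    },
                    indent=2,
                )
            )
            summary["permutation_empirical_p"] = perm.empirical_p
        else:
            logger.info("compare: permutation stage skipped (n_perm=0)")
            summary["permutation_empirical_p"] = None
        ledger["compare"] = {"genes_tested": len(gene_tests)}

        stage = "popgen"
        fst = None
        if data.genotypes is not None:
            groups = patients.set_index("sample_id")["group"]
            cohorts = patients.set_index("sample_id")["cohort"]
            coupling = config.scenario.coupling
            local_cols = [
                c for c in data.genotypes.columns
                if c.startswith(f"{coupling.target_gene}_snp") or c == coupling.snp_id
            ]
            fst = fst_scan(data.genotypes[local_cols], groups)
            fst.to_csv(outdir / "fst.tsv", sep="\t", index=False)
            rank = int(fst.index[fst["snp_id"] == coupling.snp_id][0]) + 1
            summary["coupled_snp_fst"] = float(
                fst.loc[fst["snp_id"] == coupling.snp_id, "fst"].iloc[0]
            )
            summary["coupled_snp_fst_rank"] = rank
            clustering = cluster_samples(data.genotypes, cohorts=cohorts)
            clustering.labels.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
            (outdir / "dendrogram.nwk").write_text(clustering.newick)
            from sklearn.metrics import adjusted_rand_score

            summary["cluster_ari_vs_group"] = float(
                adjusted_rand_score(groups.reindex(clustering.labels.index), clustering.labels)
            )
            ledger["popgen"] = {"n_snps": data.genotypes.shape[1], "n_gene_local_snps": len(local_cols)}

        stage = "associate"
        assoc: dict = {}
        if "CSMD3" in matrix.columns:
            asian = patients[patients["group"] == "Asian"]
            mut = matrix.reindex(asian["sample_id"])["CSMD3"].to_numpy()
            if 0 < mut.sum() < len(mut):
                km = km_logrank(
                    asian["os_months"], asian["os_event"], mut, cap_months=config.survival_cap_months
                )
                assoc["csmd3_logrank_p"] = km.p_value
                rows = []
                for lab, curve in km.curves.items():
                    curve = curve.assign(group=str(lab))
                    rows.append(curve)
                pd.concat(rows).to_csv(outdir / "survival_csmd3.tsv", sep="\t", index=False)
        if data.genotypes is not None and config.scenario.coupling is not None:
            coupling = config.scenario.coupling
            carrier = (data.genotypes[coupling.snp_id] >= 1).astype(int)
            target = matrix[coupling.target_gene].reindex(carrier.index)
            excl = exclusivity_test(carrier, target)
            assoc["snp_mutation_exclusivity_p"] = excl.p_value
            assoc["snp_mutation_co_occurrence"] = excl.counts
            if data.expression is not None:
                expr = data.expression.merge(
                    patients[["sample_id", "cohort", "stage"]], on="sample_id"
                )
                strata = []
                for _, sub in expr.groupby(["cohort", "stage"]):
                    if (sub["carrier"] == 1).sum() >= 3 and (sub["carrier"] == 0).sum() >= 3:
                        strata.append(
                            (
                                sub.loc[sub["carrier"] == 1, "expression"].mean(),
                                sub.loc[sub["carrier"] == 0, "expression"].mean(),
                            )
                        )
                if len(strata) >= 3:
                    carr, non = zip(*strata)
                    sr = paired_signed_rank(np.array(carr), np.array(non))
                    assoc["expression_signed_rank_p"] = sr.p_value
                    assoc["expression_n_strata"] = sr.n_used
        summary["association"] = assoc
        (outdir / "association.json").write_text(json.dumps(assoc, indent=2))

    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "raceblend_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "stage_ledger": ledger,
        "iteration_seeds": {
            "consensus_before": [config.seed + 1_000 + i for i in range(config.n_iterations)],
            "consensus_after": [config.seed + 2_000 + i for i in range(config.n_iterations)],
        },
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o))

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_default))
    return PipelineResult(
        outdir=outdir,
        summary=summary,
        gene_tests=gene_tests,
        balance_table=balance.table,
        consensus=after,
        fst=fst,
    )
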