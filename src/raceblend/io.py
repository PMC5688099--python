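"""Tabular input/output for the pipeline.

All files are plain TSV. Mutation tables use a MAF dialect (a column subset
of the standard Mutation Annotation Format with caller/VAF extensions);
coordinates are 1-based inclusive, the MAF convention. Every reader
validates strictly and fails loudly with the offending line or column —
nothing is coerced silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationRecord",
    "FormatError",
    "CLASSIFICATIONS",
    "NON_SILENT",
    "COHORT_TO_GROUP",
    "read_mutations",
    "write_mutations",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "read_genotypes",
    "write_genotypes",
    "read_readcounts",
    "write_readcounts",
    "build_mutation_matrix",
]

CLASSIFICATIONS = ("missense", "nonsense", "nonstop", "silent", "other")
#: Non-silent classes: missense, nonsense and non-stop substitutions.
NON_SILENT = frozenset({"missense", "nonsense", "nonstop"})

#: Fixed cohort → race-group mapping; Chinese and Vietnamese patients are
#: combined as an Asian cohort.
COHORT_TO_GROUP = {"Chinese": "Asian", "Vietnamese": "Asian", "Caucasian": "Caucasian"}
GROUPS = ("Asian", "Caucasian")
GENDERS = ("male", "female")
STAGES = ("I", "II", "III", "IV")
SMOKING = ("ever", "never", "unknown")
ALCOHOL = ("yes", "no", "unknown")

_MAF_CLASS = {
    "missense": "Missense_Mutation",
    "nonsense": "Nonsense_Mutation",
    "nonstop": "Nonstop_Mutation",
    "silent": "Silent",
    "other": "Other",
}
_MAF_CLASS_INV = {v: k for k, v in _MAF_CLASS.items()}
_MAF_CLASS_INV.update({k: k for k in CLASSIFICATIONS})

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
    "Callers",
    "VAF",
]

CLINICAL_COLUMNS = [
    "sample_id",
    "cohort",
    "age",
    "gender",
    "stage",
    "smoking",
    "alcohol",
    "os_months",
    "os_event",
]

READCOUNT_COLUMNS = [
    "sample_id",
    "cohort",
    "gene",
    "exon_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "t_ref",
    "t_alt",
    "n_ref",
    "n_alt",
]


class FormatError(ValueError):
    """A file or table violates the expected schema."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic point-mutation call for one sample.

    ``callers`` is the set of mutation callers that reported the call;
    ``vaf`` (variant allele frequency) may be ``None`` for records from
    targeted sequencing that lack it.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    classification: str
    callers: frozenset = field(default_factory=frozenset)
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise FormatError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise FormatError(f"position must be >= 1 (1-based), got {self.pos}")
        if self.classification not in CLASSIFICATIONS:
            raise FormatError(
                f"unknown classification {self.classification!r}; "
                f"expected one of {CLASSIFICATIONS}"
            )
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise FormatError(f"VAF out of [0, 1]: {self.vaf}")

    @property
    def non_silent(self) -> bool:
        return self.classification in NON_SILENT

    def site_key(self) -> tuple:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as MAF-dialect TSV (1-based inclusive coordinates)."""
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Variant_Classification": _MAF_CLASS[r.classification],
                "Tumor_Sample_Barcode": r.sample_id,
                "Callers": ";".join(sorted(r.callers)),
                "VAF": "" if r.vaf is None else f"{r.vaf:.6g}",
            }
        )
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a MAF-dialect TSV into validated :class:`MutationRecord` objects.

    Malformed rows raise :class:`FormatError` with the (1-based) line number.
    Silent records are retained (flagged via ``classification``), not dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_COLUMNS[:7] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    records: list[MutationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        d = dict(zip(df.columns, row))
        try:
            cls = _MAF_CLASS_INV.get(d["Variant_Classification"])
            if cls is None:
                raise FormatError(
                    f"unknown classification {d['Variant_Classification']!r}"
                )
            callers = frozenset(
                c for c in d.get("Callers", "").split(";") if c.strip()
            )
            vaf_raw = d.get("VAF", "")
            vaf = float(vaf_raw) if vaf_raw not in ("", "NA", ".") else None
            records.append(
                MutationRecord(
                    sample_id=d["Tumor_Sample_Barcode"],
                    gene=d["Hugo_Symbol"],
                    chrom=str(d["Chromosome"]),
                    pos=int(d["Start_Position"]),
                    ref=d["Reference_Allele"],
                    alt=d["Tumor_Seq_Allele2"],
                    classification=cls,
                    callers=callers,
                    vaf=vaf,
                )
            )
        except (FormatError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return records


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Type and validate a clinical table; derive the ``group`` column.

    The cohort → group mapping is fixed: Chinese and Vietnamese → Asian,
    Caucasian → Caucasian.
    """
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing required columns {missing}")
    out = df.copy()
    for col, vocab in [
        ("gender", GENDERS),
        ("stage", STAGES),
        ("smoking", SMOKING),
        ("alcohol", ALCOHOL),
    ]:
        if out[col].isna().any():
            raise FormatError(f"clinical column {col!r} has missing values")
        bad = set(out[col].astype(str)) - set(vocab)
        if bad:
            raise FormatError(f"clinical column {col!r} has unknown values {sorted(bad)}")
    bad_cohorts = set(out["cohort"].astype(str)) - set(COHORT_TO_GROUP)
    if bad_cohorts:
        raise FormatError(f"unknown cohort label(s) {sorted(bad_cohorts)}")
    out["age"] = pd.to_numeric(out["age"], errors="raise").astype(float)
    out["os_months"] = pd.to_numeric(out["os_months"], errors="raise").astype(float)
    if (out["os_months"] < 0).any():
        raise FormatError("negative survival time in os_months")
    out["os_event"] = pd.to_numeric(out["os_event"], errors="raise").astype(int)
    if not out["os_event"].isin([0, 1]).all():
        raise FormatError("os_event must be 0 (censored) or 1 (death)")
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    out["group"] = out["cohort"].map(COHORT_TO_GROUP)
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    return validate_clinical(df)


def write_clinical(patients: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CLINICAL_COLUMNS if c in patients.columns]
    patients[cols].to_csv(path, sep="\t", index=False)


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Write a samples × SNPs 0/1/2 matrix; missing entries become ``NA``."""
    genotypes.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    values = df.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size and not np.isin(observed, [0, 1, 2]).all():
        bad = sorted(set(observed) - {0.0, 1.0, 2.0})
        raise FormatError(f"genotype codes must be 0/1/2 or NA; found {bad}")
    return df.astype("Float64")


def write_readcounts(counts: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in READCOUNT_COLUMNS if c in counts.columns]
    counts[cols].to_csv(path, sep="\t", index=False)


def read_readcounts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    missing = [c for c in ("sample_id", "chrom", "pos", "t_ref", "t_alt") if c not in df.columns]
    if missing:
        raise FormatError(f"read-count table missing columns {missing}")
    for col in ("t_ref", "t_alt", "n_ref", "n_alt"):
        if col in df.columns and (df[col] < 0).any():
            raise FormatError(f"negative read counts in column {col!r}")
    return df


def build_mutation_matrix(
    records: Sequence[MutationRecord],
    patients: pd.DataFrame,
    non_silent_only: bool = True,
) -> pd.DataFrame:
    """Collapse per-mutation records into a sample × gene 0/1 matrix.

    A sample is 1 for a gene if at least one qualifying record exists
    (missense/nonsense/nonstop when ``non_silent_only``). Genes whose only
    records are disqualified keep an all-zero column, so the gene universe
    is visible. Records for samples absent from ``patients`` are an error.
    """
    known = set(patients["sample_id"])
    genes = sorted({r.gene for r in records})
    matrix = pd.DataFrame(
        0, index=pd.Index(patients["sample_id"], name="sample_id"), columns=genes, dtype=int
    )
    for r in records:
        if r.sample_id not in known:
            raise FormatError(f"mutation record for unknown sample {r.sample_id!r}")
        if non_silent_only and not r.non_silent:
            continue
        matrix.loc[r.sample_id, r.gene] = 1
    return matrix
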