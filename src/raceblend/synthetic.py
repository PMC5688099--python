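"""Synthetic three-population ESCC-like cohorts.

Generates clinical covariates, somatic mutation matrices, per-site
tumor/normal read counts, germline genotypes and expression with the
statistical structure the downstream analysis assumes:

* covariate distributions skewed by cohort (confounding is real);
* race-biased mutated genes with group-specific frequencies;
* cohort-specific sequencing-depth offsets (negative-binomial per exon);
* a high-divergence germline SNP whose carriers are depleted for somatic
  mutation of a target gene and show lower expression.

Everything is driven by explicit dataclass specs that serialize to YAML,
so injected effects are auditable, and every draw is deterministic given
the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io import (
    COHORT_TO_GROUP,
    MutationRecord,
    write_clinical,
    write_genotypes,
    write_mutations,
    write_readcounts,
)

__all__ = [
    "ConfigError",
    "CohortSpec",
    "GeneEffectSpec",
    "SnpCouplingSpec",
    "Scenario",
    "SyntheticData",
    "generate_clinical",
    "generate_survival",
    "generate_mutation_matrix",
    "generate_readcounts",
    "generate_genotypes_and_expression",
    "table1_cohort_specs",
    "default_scenario",
]

CALLER_NAMES = ("Muse", "MuTect2", "SomaticSniper", "Radia", "VarScan2")

#: Baseline overall-survival median (months) and administrative follow-up
#: window (months) for the exponential survival model.
BASELINE_MEDIAN_OS = 24.0
FOLLOWUP_RANGE = (6.0, 60.0)
AGE_CENTER = 60.0


class ConfigError(ValueError):
    """A generator spec is internally inconsistent."""


def _check_probs(name: str, dist: Mapping[str, float]) -> None:
    total = float(sum(dist.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name} has negative probabilities")


def _sub_seed(seed: int, stream: int) -> int:
    """Derive an independent child seed (< 2**31) from (seed, stream)."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0] % (2**31))


@dataclass
class CohortSpec:
    """Sampling spec for one patient cohort.

    ``covariate_dists`` holds categorical probabilities for gender, stage,
    smoking, alcohol, and ``age_bins`` as ``[low, high, weight]`` triples
    (weights are normalized; age is uniform within the chosen bin).
    ``mean_depth`` is the expected per-exon tumor coverage;
    ``depth_dispersion`` the negative-binomial size parameter (smaller =
    more overdispersed; ``inf`` recovers Poisson).
    """

    name: str
    n_samples: int
    covariate_dists: dict
    mean_depth: float = 80.0
    depth_dispersion: float = 3.0

    def __post_init__(self) -> None:
        if self.name not in COHORT_TO_GROUP:
            raise ConfigError(f"unknown cohort name {self.name!r}")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not self.mean_depth > 0:
            raise ConfigError("mean_depth must be > 0")
        if not self.depth_dispersion > 0:
            raise ConfigError("depth_dispersion must be > 0")
        for key in ("gender", "stage", "smoking", "alcohol"):
            if key not in self.covariate_dists:
                raise ConfigError(f"covariate_dists missing {key!r}")
            _check_probs(f"{self.name}.{key}", self.covariate_dists[key])
        bins = self.covariate_dists.get("age_bins")
        if not bins:
            raise ConfigError("covariate_dists missing 'age_bins'")
        if any(len(b) != 3 or b[1] <= b[0] or b[2] < 0 for b in bins):
            raise ConfigError("age_bins must be [low, high, weight] with high > low")
        if sum(b[2] for b in bins) <= 0:
            raise ConfigError("age_bins weights must have positive sum")

    @property
    def group(self) -> str:
        return COHORT_TO_GROUP[self.name]


@dataclass
class GeneEffectSpec:
    """Injected per-gene effect.

    ``freq_by_group`` gives the mutation probability per race group at the
    covariate reference level; ``covariate_modifiers`` shift the log-odds
    additively (categorical: level → shift; ``age``: slope per year around
    60). ``survival_hazard_ratio`` multiplies the death hazard of carriers
    (1 = no effect, <1 = protective).
    """

    gene: str
    freq_by_group: dict
    covariate_modifiers: dict | None = None
    survival_hazard_ratio: float = 1.0

    def __post_init__(self) -> None:
        for g, p in self.freq_by_group.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{self.gene}: frequency for {g} out of [0,1]: {p}")
        if not self.survival_hazard_ratio > 0:
            raise ConfigError(f"{self.gene}: hazard ratio must be > 0")


@dataclass
class SnpCouplingSpec:
    """Germline SNP coupled to somatic mutation and expression.

    ``mutation_odds_given_snp`` < 1 encodes mutual exclusivity: carriers
    have their odds of somatic mutation in ``target_gene`` multiplied by
    it. ``expression_shift`` is additive on the log-expression scale.
    """

    snp_id: str
    allele_freq_by_group: dict
    mutation_odds_given_snp: float = 1.0
    expression_shift: float = 0.0
    target_gene: str = "NFE2L2"

    def __post_init__(self) -> None:
        for g, f in self.allele_freq_by_group.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"allele frequency for {g} out of [0,1]: {f}")
        if not self.mutation_odds_given_snp > 0:
            raise ConfigError("mutation_odds_given_snp must be > 0")


# ---------------------------------------------------------------------------
# clinical covariates and survival


def _sample_categorical(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(dist.keys())
    probs = np.asarray([dist[k] for k in levels], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def generate_clinical(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Draw one clinical table (one row per sample) from a cohort spec.

    Survival is a baseline exponential (median :data:`BASELINE_MEDIAN_OS`)
    with uniform administrative censoring; gene-level hazard effects are
    applied afterwards by :func:`generate_survival`.
    """
    rng = np.random.default_rng(_sub_seed(seed, zlib.crc32(spec.name.encode()) % 10_000))
    n = spec.n_samples
    bins = spec.covariate_dists["age_bins"]
    weights = np.asarray([b[2] for b in bins], dtype=float)
    weights = weights / weights.sum()
    chosen = rng.choice(len(bins), size=n, p=weights)
    lows = np.asarray([bins[i][0] for i in chosen], dtype=float)
    highs = np.asarray([bins[i][1] for i in chosen], dtype=float)
    age = np.round(lows + rng.random(n) * (highs - lows), 1)
    df = pd.DataFrame(
        {
            "sample_id": [f"{spec.name}-{i + 1:03d}" for i in range(n)],
            "cohort": spec.name,
            "age": age,
            "gender": _sample_categorical(rng, spec.covariate_dists["gender"], n),
            "stage": _sample_categorical(rng, spec.covariate_dists["stage"], n),
            "smoking": _sample_categorical(rng, spec.covariate_dists["smoking"], n),
            "alcohol": _sample_categorical(rng, spec.covariate_dists["alcohol"], n),
        }
    )
    df["group"] = spec.group
    base_hazard = np.log(2.0) / BASELINE_MEDIAN_OS
    t = rng.exponential(1.0 / base_hazard, size=n)
    c = rng.uniform(*FOLLOWUP_RANGE, size=n)
    df["os_months"] = np.round(np.minimum(t, c), 2)
    df["os_event"] = (t <= c).astype(int)
    return df


def generate_survival(
    patients: pd.DataFrame,
    matrix: pd.DataFrame | None = None,
    effects: Sequence[GeneEffectSpec] = (),
    median_months: float = BASELINE_MEDIAN_OS,
    followup: tuple[float, float] = FOLLOWUP_RANGE,
    seed: int = 0,
) -> pd.DataFrame:
    """Redraw survival with multiplicative per-gene hazard effects.

    The hazard for sample *i* is ``log(2)/median × Π HR_g^{mut_ig}``.
    Returns a copy of ``patients`` with ``os_months``/``os_event`` replaced.
    """
    rng = np.random.default_rng(_sub_seed(seed, 77))
    n = len(patients)
    hazard = np.full(n, np.log(2.0) / median_months)
    if matrix is not None:
        aligned = matrix.reindex(patients["sample_id"]).fillna(0)
        for eff in effects:
            if eff.survival_hazard_ratio != 1.0 and eff.gene in aligned.columns:
                mutated = aligned[eff.gene].to_numpy(dtype=float)
                hazard = hazard * eff.survival_hazard_ratio**mutated
    t = rng.exponential(1.0 / hazard)
    c = rng.uniform(followup[0], followup[1], size=n)
    out = patients.copy()
    out["os_months"] = np.round(np.minimum(t, c), 2)
    out["os_event"] = (t <= c).astype(int)
    return out


# ---------------------------------------------------------------------------
# somatic mutations


def _modifier_shift(patients: pd.DataFrame, modifiers: Mapping) -> np.ndarray:
    shift = np.zeros(len(patients))
    for cov, spec in modifiers.items():
        if cov == "age":
            shift = shift + float(spec) * (patients["age"].to_numpy(dtype=float) - AGE_CENTER)
        else:
            shift = shift + patients[cov].map(dict(spec)).fillna(0.0).to_numpy(dtype=float)
    return shift


def generate_mutation_matrix(
    patients: pd.DataFrame,
    effects: Sequence[GeneEffectSpec],
    n_background_genes: int = 0,
    background_rate: float = 0.0,
    seed: int = 0,
    extra_logit: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Bernoulli sample × gene 0/1 matrix.

    Effect genes mutate with group-specific, covariate-modified probability;
    background genes (``BG0001``…) mutate at ``background_rate`` in every
    group. ``extra_logit`` maps gene → per-sample additive log-odds shift
    (used for the germline-SNP coupling). Degenerate probabilities 0 and 1
    stay exactly 0 and 1 regardless of modifiers.
    """
    if not 0.0 <= background_rate <= 1.0:
        raise ConfigError(f"background_rate out of [0,1]: {background_rate}")
    rng = np.random.default_rng(_sub_seed(seed, 101))
    groups = patients["group"].to_numpy()
    n = len(patients)
    columns: dict[str, np.ndarray] = {}
    for eff in effects:
        missing = sorted(set(groups) - set(eff.freq_by_group))
        if missing:
            raise ConfigError(
                f"gene {eff.gene}: no frequency for group(s) {missing}"
            )
        p0 = np.asarray([eff.freq_by_group[g] for g in groups], dtype=float)
        shift = np.zeros(n)
        if eff.covariate_modifiers:
            shift = shift + _modifier_shift(patients, eff.covariate_modifiers)
        if extra_logit and eff.gene in extra_logit:
            shift = shift + np.asarray(extra_logit[eff.gene], dtype=float)
        degenerate = (p0 <= 0.0) | (p0 >= 1.0)
        p = np.where(degenerate, p0, expit(logit(np.clip(p0, 1e-12, 1 - 1e-12)) + shift))
        columns[eff.gene] = (rng.random(n) < p).astype(int)
    for j in range(n_background_genes):
        columns[f"BG{j + 1:04d}"] = (rng.random(n) < background_rate).astype(int)
    return pd.DataFrame(columns, index=pd.Index(patients["sample_id"], name="sample_id"))


# ---------------------------------------------------------------------------
# read counts


_ALLELE_CYCLE = (("A", "T"), ("C", "G"), ("G", "A"), ("T", "C"))


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if not np.isfinite(dispersion):
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_readcounts(
    matrix: pd.DataFrame,
    patients: pd.DataFrame,
    spec_by_cohort: Mapping[str, CohortSpec],
    vaf_mean: float = 0.25,
    vaf_concentration: float = 6.0,
    n_germline_sites: int = 3,
    germline_carrier_rate: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site tumor/normal read counts for every sample × gene site.

    One exon (site) per gene; every sample gets a row at every site so
    per-exon depth is measurable cohort-wide. Tumor depth is negative
    binomial around the cohort's ``mean_depth``; at mutated sites the alt
    count is binomial with a Beta-distributed VAF centered at ``vaf_mean``
    (sub-clonal spread). Matched normals are ref-only except at injected
    germline-contamination sites (heterozygous in a random subset of
    samples, in tumor and normal alike) that exercise the panel-of-normals
    filter downstream.
    """
    if not 0.0 < vaf_mean <= 1.0:
        raise ConfigError(f"vaf_mean must be in (0, 1], got {vaf_mean}")
    rng = np.random.default_rng(_sub_seed(seed, 202))
    genes = list(matrix.columns)
    site_meta = {
        gene: {
            "chrom": "1",
            "pos": 10_000 + 1_000 * j,
            "ref": _ALLELE_CYCLE[j % 4][0],
            "alt": _ALLELE_CYCLE[j % 4][1],
            "exon_id": f"exon_{gene}",
        }
        for j, gene in enumerate(genes)
    }
    frames = []
    for cohort, sub in patients.groupby("cohort", sort=True):
        spec = spec_by_cohort[cohort]
        samples = sub["sample_id"].to_numpy()
        n_s, n_g = len(samples), len(genes)
        depth = _nb_depth(rng, spec.mean_depth, spec.depth_dispersion, n_s * n_g).reshape(n_s, n_g)
        mut = matrix.reindex(samples).to_numpy()
        if vaf_mean == 1.0:
            vaf = np.ones((n_s, n_g))
        else:
            a = vaf_mean * vaf_concentration
            b = (1.0 - vaf_mean) * vaf_concentration
            vaf = rng.beta(a, b, size=(n_s, n_g))
        t_alt = np.where(mut == 1, rng.binomial(depth, vaf), 0)
        n_depth = _nb_depth(rng, spec.mean_depth, spec.depth_dispersion, n_s * n_g).reshape(n_s, n_g)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(samples, n_g),
                    "cohort": cohort,
                    "gene": np.tile(genes, n_s),
                    "exon_id": np.tile([site_meta[g]["exon_id"] for g in genes], n_s),
                    "chrom": "1",
                    "pos": np.tile([site_meta[g]["pos"] for g in genes], n_s),
                    "ref": np.tile([site_meta[g]["ref"] for g in genes], n_s),
                    "alt": np.tile([site_meta[g]["alt"] for g in genes], n_s),
                    "t_ref": (depth - t_alt).ravel(),
                    "t_alt": t_alt.ravel(),
                    "n_ref": n_depth.ravel(),
                    "n_alt": 0,
                }
            )
        )
        # germline-contamination sites: heterozygous carriers show the
        # variant in both tumor and normal reads
        for j in range(n_germline_sites):
            g_depth = _nb_depth(rng, spec.mean_depth, spec.depth_dispersion, n_s)
            g_ndepth = _nb_depth(rng, spec.mean_depth, spec.depth_dispersion, n_s)
            carrier = rng.random(n_s) < germline_carrier_rate
            g_talt = np.where(carrier, rng.binomial(g_depth, 0.5), 0)
            g_nalt = np.where(carrier, rng.binomial(g_ndepth, 0.5), 0)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": samples,
                        "cohort": cohort,
                        "gene": f"GL{j + 1}",
                        "exon_id": f"germline_{j + 1}",
                        "chrom": "1",
                        "pos": 900_000 + 1_000 * j,
                        "ref": "C",
                        "alt": "T",
                        "t_ref": g_depth - g_talt,
                        "t_alt": g_talt,
                        "n_ref": g_ndepth - g_nalt,
                        "n_alt": g_nalt,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["sample_id", "pos"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotypes and expression


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, divergence: float) -> np.ndarray:
    """Population allele frequencies around ancestral ``p`` at a given
    differentiation level (Balding–Nichols Beta model)."""
    if divergence <= 0:
        return p.copy()
    f = divergence
    return rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)


def generate_genotypes_and_expression(
    patients: pd.DataFrame,
    coupling: SnpCouplingSpec,
    n_neutral_snps: int = 300,
    neutral_divergence: float = 0.10,
    within_asian_divergence: float = 0.01,
    n_gene_local_snps: int = 30,
    local_divergence: float = 0.02,
    baseline_expression: float = 10.0,
    expression_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hardy–Weinberg genotypes (0/1/2) plus carrier-shifted expression.

    Two SNP classes are simulated: a genome-wide neutral panel at
    ``neutral_divergence`` between Asian and Caucasian groups (Chinese and
    Vietnamese drawn with small within-Asian divergence) that carries the
    population structure, and a low-divergence set local to the coupled
    SNP's gene, among which the coupled SNP should stand out. Expression is
    ``baseline + expression_shift × carrier + Gaussian noise``.
    """
    rng = np.random.default_rng(_sub_seed(seed, 303))
    cohorts = patients["cohort"].to_numpy()
    groups = patients["group"].to_numpy()
    n = len(patients)

    def hw_draw(freq_per_sample: np.ndarray) -> np.ndarray:
        return rng.binomial(2, freq_per_sample)

    data: dict[str, np.ndarray] = {}
    anc = rng.uniform(0.1, 0.9, size=n_neutral_snps)
    for j in range(n_neutral_snps):
        asian_p = float(_balding_nichols(rng, np.array([anc[j]]), neutral_divergence)[0])
        cauc_p = float(_balding_nichols(rng, np.array([anc[j]]), neutral_divergence)[0])
        by_cohort = {
            "Chinese": float(_balding_nichols(rng, np.array([asian_p]), within_asian_divergence)[0]),
            "Vietnamese": float(_balding_nichols(rng, np.array([asian_p]), within_asian_divergence)[0]),
            "Caucasian": cauc_p,
        }
        freq = np.asarray([by_cohort[c] for c in cohorts])
        data[f"snp{j + 1:04d}"] = hw_draw(freq)
    anc_local = rng.uniform(0.1, 0.9, size=n_gene_local_snps)
    for j in range(n_gene_local_snps):
        by_group = {
            "Asian": float(_balding_nichols(rng, np.array([anc_local[j]]), local_divergence)[0]),
            "Caucasian": float(_balding_nichols(rng, np.array([anc_local[j]]), local_divergence)[0]),
        }
        freq = np.asarray([by_group[g] for g in groups])
        data[f"{coupling.target_gene}_snp{j + 1:02d}"] = hw_draw(freq)
    missing_groups = sorted(set(groups) - set(coupling.allele_freq_by_group))
    if missing_groups:
        raise ConfigError(f"coupling lacks allele frequency for group(s) {missing_groups}")
    freq = np.asarray([coupling.allele_freq_by_group[g] for g in groups])
    data[coupling.snp_id] = hw_draw(freq)
    genotypes = pd.DataFrame(data, index=pd.Index(patients["sample_id"], name="sample_id"))

    carrier = (genotypes[coupling.snp_id] >= 1).astype(int)
    expression = pd.DataFrame(
        {
            "sample_id": patients["sample_id"].to_numpy(),
            "carrier": carrier.to_numpy(),
            "expression": baseline_expression
            + coupling.expression_shift * carrier.to_numpy()
            + rng.normal(0.0, expression_sd, size=n),
        }
    )
    return genotypes, expression


# ---------------------------------------------------------------------------
# scenario orchestration


@dataclass
class Scenario:
    """Complete generator configuration for one synthetic study."""

    cohorts: list
    effects: list = field(default_factory=list)
    coupling: SnpCouplingSpec | None = None
    n_background_genes: int = 150
    background_rate: float = 0.05
    vaf_mean: float = 0.25
    vaf_concentration: float = 6.0
    n_neutral_snps: int = 300
    neutral_divergence: float = 0.10
    within_asian_divergence: float = 0.01
    n_gene_local_snps: int = 30
    local_divergence: float = 0.02
    survival_median_months: float = BASELINE_MEDIAN_OS
    n_germline_sites: int = 3
    germline_carrier_rate: float = 0.15

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohorts"] = [asdict(c) for c in self.cohorts]
        d["effects"] = [asdict(e) for e in self.effects]
        d["coupling"] = asdict(self.coupling) if self.coupling else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Scenario":
        d = dict(d)
        d["cohorts"] = [CohortSpec(**c) for c in d["cohorts"]]
        d["effects"] = [GeneEffectSpec(**e) for e in d.get("effects", [])]
        coup = d.get("coupling")
        d["coupling"] = SnpCouplingSpec(**coup) if coup else None
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Scenario":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def generate(self, seed: int) -> "SyntheticData":
        clinical = pd.concat(
            [generate_clinical(spec, _sub_seed(seed, 10 + i)) for i, spec in enumerate(self.cohorts)],
            ignore_index=True,
        )
        genotypes = expression = None
        extra_logit = None
        if self.coupling is not None:
            genotypes, expression = generate_genotypes_and_expression(
                clinical,
                self.coupling,
                n_neutral_snps=self.n_neutral_snps,
                neutral_divergence=self.neutral_divergence,
                within_asian_divergence=self.within_asian_divergence,
                n_gene_local_snps=self.n_gene_local_snps,
                local_divergence=self.local_divergence,
                seed=_sub_seed(seed, 20),
            )
            carrier = (genotypes[self.coupling.snp_id] >= 1).to_numpy(dtype=float)
            extra_logit = {
                self.coupling.target_gene: np.log(self.coupling.mutation_odds_given_snp) * carrier
            }
        matrix = generate_mutation_matrix(
            clinical,
            self.effects,
            n_background_genes=self.n_background_genes,
            background_rate=self.background_rate,
            seed=_sub_seed(seed, 30),
            extra_logit=extra_logit,
        )
        clinical = generate_survival(
            clinical,
            matrix,
            self.effects,
            median_months=self.survival_median_months,
            seed=_sub_seed(seed, 40),
        )
        readcounts = generate_readcounts(
            matrix,
            clinical,
            {c.name: c for c in self.cohorts},
            vaf_mean=self.vaf_mean,
            vaf_concentration=self.vaf_concentration,
            n_germline_sites=self.n_germline_sites,
            germline_carrier_rate=self.germline_carrier_rate,
            seed=_sub_seed(seed, 50),
        )
        return SyntheticData(
            scenario=self,
            seed=seed,
            clinical=clinical,
            matrix=matrix,
            readcounts=readcounts,
            genotypes=genotypes,
            expression=expression,
        )


@dataclass
class SyntheticData:
    """Bundle of the generated tables for one seed."""

    scenario: Scenario
    seed: int
    clinical: pd.DataFrame
    matrix: pd.DataFrame
    readcounts: pd.DataFrame
    genotypes: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None

    def mutation_records(
        self, single_caller_rate: float = 0.05, silent_record_rate: float = 0.10
    ) -> list[MutationRecord]:
        """Derive MAF-style records from read-count rows with alt support.

        A mutated matrix entry denotes non-silent mutation status, so its
        record is always missense/nonsense/nonstop; silent records are an
        *additional* stream (at the neighbouring position) so downstream
        silent handling is exercised without eroding injected signal.
        Caller sets are sampled from the five-caller universe; a small
        fraction of records get a single caller to exercise the ≥2-caller
        merge. Germline-contamination sites flow through as candidate
        calls (named ``GL*``) so the panel-of-normals filter has something
        to remove.
        """
        rng = np.random.default_rng(_sub_seed(self.seed, 60))
        candidates = self.readcounts[self.readcounts["t_alt"] > 0]
        records = []
        class_levels = np.array(["missense", "nonsense", "nonstop"])
        class_probs = np.array([0.82, 0.148, 0.032])

        def draw_callers() -> frozenset:
            if rng.random() < single_caller_rate:
                return frozenset(rng.choice(CALLER_NAMES, size=1))
            k = int(rng.integers(2, len(CALLER_NAMES) + 1))
            return frozenset(rng.choice(CALLER_NAMES, size=k, replace=False))

        for row in candidates.itertuples(index=False):
            depth = row.t_ref + row.t_alt
            vaf = float(row.t_alt) / depth if depth > 0 else None
            records.append(
                MutationRecord(
                    sample_id=row.sample_id,
                    gene=row.gene,
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    classification=str(rng.choice(class_levels, p=class_probs)),
                    callers=draw_callers(),
                    vaf=vaf,
                )
            )
            if rng.random() < silent_record_rate:
                records.append(
                    MutationRecord(
                        sample_id=row.sample_id,
                        gene=row.gene,
                        chrom=str(row.chrom),
                        pos=int(row.pos) + 1,
                        ref=row.ref,
                        alt=row.alt,
                        classification="silent",
                        callers=draw_callers(),
                        vaf=vaf,
                    )
                )
        return records

    def write(self, outdir: str | Path) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "clinical": outdir / "clinical.tsv",
            "mutations": outdir / "mutations.maf.tsv",
            "readcounts": outdir / "readcounts.tsv",
            "scenario": outdir / "scenario.yaml",
        }
        write_clinical(self.clinical, paths["clinical"])
        write_mutations(self.mutation_records(), paths["mutations"])
        write_readcounts(self.readcounts, paths["readcounts"])
        self.scenario.to_yaml(paths["scenario"])
        if self.genotypes is not None:
            paths["genotypes"] = outdir / "genotypes.tsv"
            write_genotypes(self.genotypes, paths["genotypes"])
        if self.expression is not None:
            paths["expression"] = outdir / "expression.tsv"
            self.expression.to_csv(paths["expression"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# default study conditions


def _smooth(dist: Mapping[str, float], floor: float = 0.02) -> dict:
    """Floor structural zeros so no covariate level perfectly predicts a
    cohort, then renormalize."""
    raised = {k: max(float(v), floor) for k, v in dist.items()}
    total = sum(raised.values())
    return {k: v / total for k, v in raised.items()}


def _counts(**kv: float) -> dict:
    total = sum(kv.values())
    return {k: v / total for k, v in kv.items()}


def table1_cohort_specs(
    caucasian_depth: float = 80.0,
    vietnamese_depth: float = 80.0,
    chinese_depth: float = 160.0,
    depth_dispersion: float = 3.0,
    n_caucasian: int = 39,
    n_vietnamese: int = 41,
    n_chinese: int = 78,
) -> list[CohortSpec]:
    """The three WES cohorts with their published covariate skews.

    Category weights follow the published cohort characteristics table
    (gender, age decade, stage, smoking, alcohol per cohort); zero cells
    are floored (see :func:`_smooth`). The Chinese cohort carries the 2×
    depth offset that motivates harmonization.
    """
    age_bins = lambda *w: [[30, 40, w[0]], [40, 50, w[1]], [50, 60, w[2]], [60, 70, w[3]], [70, 80, w[4]], [80, 90, w[5]]]
    caucasian = CohortSpec(
        name="Caucasian",
        n_samples=n_caucasian,
        covariate_dists={
            "gender": _counts(male=29, female=10),
            "age_bins": age_bins(0, 6, 19, 9, 4, 4),
            "stage": _smooth(_counts(I=6, II=17, III=14, IV=2)),
            "smoking": _smooth(_counts(ever=25, never=11, unknown=3)),
            "alcohol": _smooth(_counts(yes=25, no=12, unknown=2)),
        },
        mean_depth=caucasian_depth,
        depth_dispersion=depth_dispersion,
    )
    vietnamese = CohortSpec(
        name="Vietnamese",
        n_samples=n_vietnamese,
        covariate_dists={
            "gender": _counts(male=39, female=2),
            "age_bins": age_bins(2, 1, 15, 9, 4, 0.5),
            "stage": _smooth(_counts(I=0, II=31, III=9, IV=1)),
            "smoking": _smooth(_counts(ever=22, never=19, unknown=0)),
            "alcohol": _smooth(_counts(yes=30, no=11, unknown=0)),
        },
        mean_depth=vietnamese_depth,
        depth_dispersion=depth_dispersion,
    )
    chinese = CohortSpec(
        name="Chinese",
        n_samples=n_chinese,
        covariate_dists={
            "gender": _counts(male=65, female=13),
            "age_bins": age_bins(0, 11, 35, 27, 5, 0.5),
            "stage": _smooth(_counts(I=0, II=63, III=15, IV=0)),
            "smoking": _smooth(_counts(ever=46, never=32, unknown=0)),
            "alcohol": _smooth(_counts(yes=36, no=42, unknown=0)),
        },
        mean_depth=chinese_depth,
        depth_dispersion=depth_dispersion,
    )
    return [caucasian, vietnamese, chinese]


def default_scenario() -> Scenario:
    """The default three-cohort study: six race-biased genes (three higher
    in Asians, three in Caucasians), one prognostic gene, two confounded
    null genes, and the coupled high-divergence 5′UTR SNP."""
    effects = [
        GeneEffectSpec("TP53", {"Asian": 0.90, "Caucasian": 0.45}),
        GeneEffectSpec("NFE2L2", {"Asian": 0.45, "Caucasian": 0.02}),
        GeneEffectSpec("EP300", {"Asian": 0.25, "Caucasian": 0.01}),
        GeneEffectSpec("KRTAP9-1", {"Asian": 0.01, "Caucasian": 0.28}),
        GeneEffectSpec("LRFN5", {"Asian": 0.01, "Caucasian": 0.28}),
        GeneEffectSpec("MAP2", {"Asian": 0.01, "Caucasian": 0.28}),
        GeneEffectSpec("CSMD3", {"Asian": 0.30, "Caucasian": 0.30}, survival_hazard_ratio=0.45),
        GeneEffectSpec(
            "NOTCH1",
            {"Asian": 0.25, "Caucasian": 0.25},
            covariate_modifiers={"smoking": {"ever": 0.9, "never": -0.2}},
        ),
        GeneEffectSpec(
            "PIK3CA",
            {"Asian": 0.20, "Caucasian": 0.20},
            covariate_modifiers={"alcohol": {"yes": 0.8}},
        ),
    ]
    coupling = SnpCouplingSpec(
        snp_id="rs113671272",
        allele_freq_by_group={"Asian": 0.45, "Caucasian": 0.003},
        mutation_odds_given_snp=0.2,
        expression_shift=-1.0,
        target_gene="NFE2L2",
    )
    return Scenario(cohorts=table1_cohort_specs(), effects=effects, coupling=coupling)
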