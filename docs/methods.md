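# Methods

## The statistical problem

Comparing per-gene somatic mutation frequencies between patient
populations is doubly confounded. Technically, a cohort sequenced deeper
detects more (especially sub-clonal) mutations, inflating its apparent
burden. Biologically, clinical covariates that differ between populations
— age, gender, tumor stage, smoking and alcohol history — themselves
shift mutation probabilities, so a naive two-group test attributes
covariate effects to ancestry. raceblend addresses the first with
depth harmonization and the second with propensity-score matching
weights; both stages are testable end to end against a synthetic
generator whose injected structure is known exactly.

## Depth harmonization

Per-site tumor read counts carry an exon label. For each exon, the
per-cohort mean depth is computed and every cohort is binomially thinned
toward the minimum cohort mean (`fraction = target / mean`, the cohort
already at the minimum keeping fraction 1). Because fractions are
estimated from, and applied to, the same counts, realized thinned means
agree up to thinning noise; the residual pairwise standardized difference
`100·|m₁−m₂| / sqrt((v₁+v₂)/2)` is measured empirically and sits well
below the 10% balance criterion in the standard scenarios (≈5–7% at the
default dispersion). The pooled-variance form of the standardized
difference is used throughout; the balanced statistic is the per-exon
*mean* depth (configurable in principle — the median is a reasonable
alternative, but the mean is what binomial thinning controls exactly).

Thinning is applied at the count level, independently to reference and
alternate reads — statistically equivalent to read-level downsampling for
any caller that decides on counts, and the package models no reads. The
thin-and-call cycle runs 10 times with seeds `base_seed + i` (recorded in
the run manifest); a site is a **consensus call** when called in ≥ 8
iterations. Candidate records first pass a ≥ 2-caller merge and a
panel-of-normals filter (sites with variant evidence in *more than one*
normal are removed — a site in exactly one normal survives).

The built-in caller declares a site mutated when `t_alt ≥ 4`,
`VAF ≥ 0.05`, depth ≥ 10 and the matched normal's alt fraction is below
0.05. These thresholds are declared defaults, not estimates of any
external pipeline; the strand-bias flag on `CallerParams` is accepted but
is a documented no-op because the count model carries no strand
information. Monotonicity holds by construction: thinning never increases
a count, and lowering depth can only lose calls in expectation.

The validation-rate operation reports
`100 × confirmed / assessed` to one decimal, where *assessed* are WES
calls whose site reaches ≥ 200× targeted depth and *confirmed* are those
also called in the targeted data; zero assessable sites leave the rate
undefined (an error, not a silent 0).

## Propensity adjustment and the weighted test

The propensity model is a maximum-likelihood logistic regression of group
membership (Asian vs Caucasian) on age (linear, in years) and
indicator-coded gender, stage, smoking and alcohol. "Unknown"
smoking/alcohol levels are kept as explicit indicator levels rather than
dropping samples. Fitted probabilities are clipped to
[10⁻⁶, 1−10⁻⁶]; complete separation raises an explicit error suggesting
covariate reduction, and single-level covariates are dropped with a
warning. The matching weight `min(e, 1−e)/P(own group)` lies in (0, 1]
and emulates 1:1 pair matching: a sample whose group is locally
over-represented is down-weighted toward its scarcer counterparts.
Balance is declared when the weighted propensity-score standardized
difference is below 10%; the per-covariate table is reported alongside.

The weighted chi-squared statistic is Pearson's statistic on the 2×2
table of weighted mutation proportions rescaled to each group's Kish
effective sample size `n_eff = (Σw)²/Σw²`. This construction was chosen
because it reduces *exactly* to the classical uncorrected Pearson test at
unit weights (the correctness anchor, asserted in the tests) and because
the effective-sample-size rescaling guards against anti-conservative
inference under unequal weights. Its finite-sample level is verified by
simulation, not assumed: under the confounded null (mutation driven only
by covariates, covariates skewed by cohort) the measured type-I error at
α = 0.05 is ≈ 0.04 with 1000 replicates at n = 200/group, while the
unweighted test rejects at ≈ 0.48. Users should know the exact variance
construction of a "weighted chi-squared" is not standardized across
software; the reduction property and the measured calibration are this
package's contract.

Genes reaching a weighted frequency of 0.05 in at least one group are
tested (the floor mirrors the usual ≥ 5% display threshold and is
configurable); Benjamini–Hochberg controls the FDR across tested genes at
0.1. The permutation check shuffles race labels, *refits the propensity
model inside every permutation*, reruns the full scan, and reports
`(1 + #{permuted ≥ observed}) / (n_perm + 1)`; permutations whose refit
separates are resampled and counted.

Effective sample size is the price of weighting: at the demo scale
(158 samples, 119 Asian / 39 Caucasian) the matching weights leave
n_eff ≈ 50 and ≈ 30. Combined with calling attenuation this means the
weakest injected effects do not clear FDR ≤ 0.1 in every realization of
the demo; the dedicated recovery conditions (odds ratio 3 at frequency
≥ 0.1, n = 500/group, 200 null genes) recover all six injected genes
with correct direction in ≥ 95% of runs.

## Germline-side analyses

Per-SNP differentiation uses Hudson's two-population estimator,
`[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂)+p₂(1−p₁)]`
with allele counts n (2 × diploid samples); a zero denominator defines
Fst = 0, and negative raw values are clipped to 0 for reporting while the
raw value is retained. The estimator choice (frequency-based, two
populations) fits a panel-vs-panel comparison; the test suite
cross-checks it against an independently coded Weir–Cockerham oracle on
island-model simulations (agreement within 0.02 at every divergence
level — a known, documented divergence risk between Fst estimators).

Genotypes are coded 0/1/2; SNPs enter the clustering matrix only when
covered ≥ 8× in *every* sample at base quality ≥ 15. Clustering is
agglomerative with Euclidean distance and average linkage (both
configurable — recovery of the population split, not dendrogram shape,
is the contract), cut at two clusters; the dendrogram is exported as
Newick. Carrier status at a single SNP can alternatively be inferred from
off-target reads: below 3 reads the sample is uncallable, otherwise one
alternate-supporting read suffices (deliberately lenient, threshold
exposed).

Survival uses the Kaplan–Meier product-limit estimate and the standard
aggregated-risk-set log-rank test, with observations administratively
censored at 36 months before estimation. Pairwise mutual exclusivity is
an exact fixed-margin test: conditioning on both feature margins, the
p-value is the lower hypergeometric tail of the co-occurrence count —
exact and deterministic, replacing MCMC-based marginal-probability
machinery for pairs (triple-wise exclusivity is out of scope); samples
uncallable at a feature are excluded from the evaluable universe first.
The paired expression comparison uses the Wilcoxon signed-rank test
(exact null for ≤ 25 informative pairs, normal approximation beyond),
chosen over the rank-sum because the comparison is paired by stratum.

## The synthetic generator

The generator emulates the study conditions, not raw sequencing:

* **Cohorts** — Caucasian n=39, Vietnamese n=41, Chinese n=78, with
  published covariate compositions used as sampling weights (age-decade
  bins, gender, stage, smoking, alcohol; "unknown" levels generated at
  their tabulated rates). Structural zero cells (e.g. stage I absent in
  the Asian cohorts) are floored at 0.02 and renormalized: a level
  perfectly predicting the cohort would make the propensity MLE
  degenerate by construction rather than by data. The extracted age-bin
  counts for two cohorts do not sum exactly to the cohort sizes; bins are
  treated as weights and normalized.
* **Depth** — negative-binomial per exon (default mean 80×, Chinese
  160×, dispersion 3), matching long-tailed exome coverage; Poisson is
  the dispersion → ∞ limit.
* **VAF** — Beta centered at 0.25 with concentration 6, giving
  sub-clonal spread while keeping the callable fraction consistent with a
  ~95% validation-rate regime.
* **Effects** — per-gene group frequencies with optional additive
  log-odds covariate modifiers (the injected confounding is stated in the
  scenario config, hence auditable) and a multiplicative survival hazard
  ratio. Modifier magnitudes are scenario parameters, not estimates.
* **Germline SNPs** — Hardy–Weinberg draws from Balding–Nichols
  frequencies: a genome-wide panel at divergence 0.10 between the race
  groups (within-Asian divergence 0.01) carrying the clustering
  structure, plus a low-divergence (0.02) gene-local set within which the
  coupled SNP (Asian allele frequency 0.45 vs 0.003) must rank first —
  mirroring a ranking among one gene's SNPs rather than genome-wide.
  Carriers multiply the target gene's somatic-mutation odds by 0.2
  (exclusivity) and shift log-expression by −1.
* **Records** — a mutated matrix entry means non-silent mutation status;
  derived MAF records are missense/nonsense/nonstop with five-caller
  support (5% single-caller artifacts exercise the merge), silent records
  are an additional stream, and injected germline-contamination sites
  appear in multiple normals to exercise the panel filter.

What the generator does *not* model: reads (counts are the lowest level),
strand bias, indels, mutational signatures, linkage disequilibrium among
SNPs, per-gene background mutation-rate heterogeneity, and
covariate-dependent sequencing depth. Passing tests therefore demonstrate
the statistical machinery under the stated sampling models — calibration,
recovery, balance, estimator agreement — not robustness to artifacts
outside those models.

## Numerical choices and degenerate inputs

Determinism is a contract: every operation takes a seed, child streams
are derived via `SeedSequence(seed, stream)`, and identical seeds yield
byte-identical outputs (asserted for the whole pipeline). Degenerate
cases are defined, not crashed on: zero tumor depth is never called;
all-mutated or all-wildtype tables give statistic 0 / p 1; a zero
exclusivity margin gives p 1 with a degeneracy flag; all-zero paired
differences give p 1; zero pooled variance with unequal means reports an
infinite standardized difference. Ties in clustering produce zero-height
merges with stable (index-ordered) layout. Injected probabilities of
exactly 0 or 1 are preserved exactly regardless of modifiers.

## Problem sizes

The standard experiment sizes — 1000 replicates at n = 200/group for the
null calibration, 20 runs at n = 500/group for recovery, ~45 exons × 158
samples for harmonization, 331 SNPs × 158 samples for the germline
analyses — were chosen so the full suite and the reproduction script each
complete in well under a minute to a few minutes on a single CPU while
keeping Monte-Carlo error small relative to the asserted margins
(binomial SE ≈ 0.007 on a 0.05 rejection rate at 1000 replicates).
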