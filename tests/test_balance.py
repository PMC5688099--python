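import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from raceblend.balance import (
    SeparationError,
    check_balance,
    fit_propensity,
    matching_weight,
    permutation_significance,
    race_biased_genes,
    standardized_difference,
    weighted_chisq,
)
from raceblend.synthetic import GeneEffectSpec, generate_mutation_matrix


class TestPropensity:
    def test_intercept_only_scores_equal_prevalence(self, patients_small):
        res = fit_propensity(patients_small, covariates=())
        prevalence = (patients_small["group"] == "Asian").mean()
        assert np.allclose(res["score"], prevalence, atol=1e-6)

    def test_scores_strictly_inside_unit_interval(self, patients_small):
        res = fit_propensity(patients_small)
        assert ((res["score"] > 0) & (res["score"] < 1)).all()

    def test_matching_weight_formula(self):
        # score 0.8 for a sample of the high-probability group → 0.25;
        # for its counterpart in the other group → 1.0
        assert matching_weight(np.array([0.8]), np.array([True]))[0] == pytest.approx(0.25)
        assert matching_weight(np.array([0.8]), np.array([False]))[0] == pytest.approx(1.0)
        assert matching_weight(np.array([0.5]), np.array([True]))[0] == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(score=st.floats(1e-6, 1 - 1e-6), treated=st.booleans())
    def test_weights_in_unit_interval(self, score, treated):
        w = matching_weight(np.array([score]), np.array([treated]))[0]
        assert 0 < w <= 1

    def test_extreme_sample_downweighted_vs_counterpart(self):
        # at the same score, the sample from the locally-common group gets
        # the smaller weight (it has excess counterparts to match)
        e = np.array([0.9])
        assert matching_weight(e, np.array([True]))[0] < matching_weight(e, np.array([False]))[0]

    def test_complete_separation_raises(self, patients_small):
        df = patients_small.copy()
        df["stage"] = np.where(df["group"] == "Asian", "I", "IV")  # perfect predictor
        with pytest.raises(SeparationError, match="separation"):
            fit_propensity(df, covariates=("stage",))

    def test_single_level_covariate_dropped_with_warning(self, patients_small):
        df = patients_small.copy()
        df["gender"] = "male"
        with pytest.warns(UserWarning, match="single level"):
            res = fit_propensity(df, covariates=("age", "gender"))
        assert len(res) == len(df)


class TestStandardizedDifference:
    def test_identical_distributions_zero(self):
        x = np.arange(10.0)
        assert standardized_difference(x, x) == 0.0

    def test_closed_form_means_zero_one_unit_variance(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 1, 200_000)
        x2 = rng.normal(1, 1, 200_000)
        assert standardized_difference(x1, x2) == pytest.approx(100.0, abs=1.5)

    def test_exact_two_point_example(self):
        # two-point samples with means 0 and 1, variances exactly 1
        x1 = np.array([-1.0, 1.0])  # mean 0, var 2 → use 4 points for var 1
        x1 = np.array([-1.0, -1.0, 1.0, 1.0]) * np.sqrt(3 / 4)  # var (n-1 denom) = 1
        x2 = x1 + 1.0
        assert standardized_difference(x1, x2) == pytest.approx(100.0)

    def test_weights_can_remove_confounding(self):
        # reweighting equalizes a two-point covariate: weighted diff < raw
        x1 = np.array([0.0, 0.0, 0.0, 1.0])
        x2 = np.array([0.0, 1.0, 1.0, 1.0])
        w1 = np.array([1.0, 1.0, 1.0, 3.0])
        w2 = np.array([3.0, 1.0, 1.0, 1.0])
        raw = standardized_difference(x1, x2)
        weighted = standardized_difference(x1, x2, w1, w2)
        assert weighted < raw
        assert weighted == pytest.approx(0.0, abs=1e-9)

    def test_zero_variance_unequal_means_infinite(self):
        assert standardized_difference([1, 1], [2, 2]) == np.inf

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            standardized_difference([1.0], [1.0, 2.0])


class TestBalanceCheck:
    def test_identical_cohorts_balanced_before_weighting(self, patients_small):
        # covariates drawn identically for both groups → already balanced
        prop = fit_propensity(patients_small)
        report = check_balance(patients_small, prop)
        assert report.balanced

    def test_zero_threshold_never_balanced_without_exact_equality(self, patients_small):
        prop = fit_propensity(patients_small)
        report = check_balance(patients_small, prop, threshold_pct=0.0)
        assert not report.balanced

    def test_skewed_cohorts_balance_only_after_weighting(self):
        from raceblend.experiments import _two_group_cohorts
        from raceblend.synthetic import generate_clinical

        cohorts = _two_group_cohorts(250)
        patients = pd.concat(
            [generate_clinical(c, 3 + i) for i, c in enumerate(cohorts)], ignore_index=True
        )
        prop = fit_propensity(patients)
        report = check_balance(patients, prop)
        assert report.score_std_diff_before > 10.0
        assert report.score_std_diff_after < 10.0
        covs = report.table[report.table["covariate"] != "propensity_score"]
        assert covs["std_diff_after_pct"].max() < covs["std_diff_before_pct"].max()


class TestWeightedChisq:
    def test_unit_weights_reduce_to_classical_pearson(self):
        rng = np.random.default_rng(1)
        mutated = rng.integers(0, 2, 120)
        group = np.where(rng.random(120) < 0.5, "Asian", "Caucasian")
        res = weighted_chisq(mutated, group, np.ones(120))
        table = pd.crosstab(group, mutated)
        stat, p, _, _ = chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_equal_weighted_frequencies_give_zero(self):
        mutated = np.array([1, 0, 1, 0])
        group = np.array(["Asian", "Asian", "Caucasian", "Caucasian"])
        res = weighted_chisq(mutated, group, np.ones(4))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_all_mutated_degenerate(self):
        res = weighted_chisq(np.ones(10), np.array(["Asian"] * 5 + ["Caucasian"] * 5), np.ones(10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_total_weight_rejected(self):
        group = np.array(["Asian"] * 5 + ["Caucasian"] * 5)
        w = np.array([1.0] * 5 + [0.0] * 5)
        with pytest.raises(ValueError, match="zero total weight"):
            weighted_chisq(np.ones(10), group, w)


class TestRaceBiasedGenes:
    def test_single_gene_fdr_equals_p(self, patients_small):
        matrix = generate_mutation_matrix(
            patients_small, [GeneEffectSpec("G", {"Asian": 0.6, "Caucasian": 0.2})], seed=4
        )
        res = race_biased_genes(matrix, patients_small, require_balance=False)
        assert len(res) == 1
        assert res["fdr"].iloc[0] == pytest.approx(res["p_value"].iloc[0])

    def test_min_freq_one_tests_nothing(self, patients_small):
        matrix = generate_mutation_matrix(
            patients_small, [GeneEffectSpec("G", {"Asian": 0.5, "Caucasian": 0.5})], seed=4
        )
        with pytest.warns(UserWarning, match="frequency filter"):
            res = race_biased_genes(matrix, patients_small, min_freq=1.0, require_balance=False)
        assert len(res) == 0

    def test_unit_weight_reduction_matches_classical_scan(self, patients_small):
        # with forced unit weights the scan is a classical per-gene
        # chi-squared + Benjamini-Hochberg analysis
        effects = [
            GeneEffectSpec("G1", {"Asian": 0.6, "Caucasian": 0.15}),
            GeneEffectSpec("G2", {"Asian": 0.3, "Caucasian": 0.3}),
        ]
        matrix = generate_mutation_matrix(patients_small, effects, 5, 0.2, seed=9)
        prop = fit_propensity(patients_small, covariates=())
        prop["matching_weight"] = 1.0
        res = race_biased_genes(matrix, patients_small, prop, require_balance=False)
        for _, row in res.iterrows():
            obs = matrix[row["gene"]].to_numpy()
            table = pd.crosstab(patients_small["group"], obs)
            if table.shape == (2, 2):
                stat, p, _, _ = chi2_contingency(table, correction=False)
                assert row["statistic"] == pytest.approx(stat)
                assert row["p_value"] == pytest.approx(p)

    def test_direction_labels_follow_weighted_frequencies(self, patients_small):
        effects = [
            GeneEffectSpec("UP_A", {"Asian": 0.7, "Caucasian": 0.1}),
            GeneEffectSpec("UP_C", {"Asian": 0.1, "Caucasian": 0.7}),
        ]
        matrix = generate_mutation_matrix(patients_small, effects, seed=2)
        res = race_biased_genes(matrix, patients_small, require_balance=False).set_index("gene")
        assert res.loc["UP_A", "direction"] == "asian_higher"
        assert res.loc["UP_C", "direction"] == "caucasian_higher"


class TestPermutation:
    def test_single_forced_permutation_arithmetic(self, patients_small):
        matrix = generate_mutation_matrix(
            patients_small, [GeneEffectSpec("G", {"Asian": 0.8, "Caucasian": 0.05})], seed=4
        )
        res = permutation_significance(matrix, patients_small, n_perm=1, seed=0)
        assert res.empirical_p in (0.5, 1.0)

    def test_reentrant_with_same_seed(self, patients_small):
        matrix = generate_mutation_matrix(
            patients_small, [GeneEffectSpec("G", {"Asian": 0.6, "Caucasian": 0.1})], 10, 0.2, seed=4
        )
        a = permutation_significance(matrix, patients_small, n_perm=8, seed=3)
        b = permutation_significance(matrix, patients_small, n_perm=8, seed=3)
        assert np.array_equal(a.permuted_counts, b.permuted_counts)
        assert a.empirical_p == b.empirical_p

    def test_strong_effect_beats_all_permutations(self, patients_small):
        effects = [
            GeneEffectSpec(f"G{i}", {"Asian": 0.85, "Caucasian": 0.02}) for i in range(3)
        ]
        matrix = generate_mutation_matrix(patients_small, effects, 20, 0.1, seed=5)
        res = permutation_significance(matrix, patients_small, n_perm=19, seed=1)
        assert res.observed_significant >= 3
        assert res.empirical_p == pytest.approx(1 / 20)

    def test_invalid_n_perm(self, patients_small):
        matrix = generate_mutation_matrix(
            patients_small, [GeneEffectSpec("G", {"Asian": 0.5, "Caucasian": 0.5})], seed=1
        )
        with pytest.raises(ValueError):
            permutation_significance(matrix, patients_small, n_perm=0)
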