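import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from raceblend.harmonize import (
    CallerParams,
    call_site,
    call_sites,
    compute_downsampling_fractions,
    consensus_calls,
    depth_balance_report,
    exon_depth_summary,
    filter_germline_panel,
    merge_callers,
    thin_counts,
    validation_rate,
)
from raceblend.io import MutationRecord


def rec(sample="S1", pos=100, callers=("Muse", "MuTect2")):
    return MutationRecord(
        sample_id=sample, gene="G", chrom="1", pos=pos, ref="C", alt="T",
        classification="missense", callers=frozenset(callers),
    )


class TestMergeCallers:
    def test_single_caller_dropped(self):
        assert merge_callers([rec(callers=("MuTect2",))]) == []

    def test_five_callers_kept(self):
        r = rec(callers=("Muse", "MuTect2", "SomaticSniper", "Radia", "VarScan2"))
        assert merge_callers([r]) == [r]

    def test_min_callers_one_is_identity(self):
        records = [rec(callers=("Muse",)), rec(pos=101)]
        assert merge_callers(records, min_callers=1) == records

    def test_empty_caller_set_rejected(self):
        with pytest.raises(ValueError, match="empty caller set"):
            merge_callers([rec(callers=())])


class TestGermlinePanel:
    def normals(self, n_samples, pos=100):
        return pd.DataFrame(
            {
                "sample_id": [f"N{i}" for i in range(n_samples)],
                "chrom": "1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
            }
        )

    def test_site_in_two_normals_removed(self):
        kept, log = filter_germline_panel([rec()], self.normals(2))
        assert kept == []
        assert log["n_normals"].tolist() == [2]

    def test_site_in_one_normal_kept(self):
        # the criterion is strictly "more than one normal"
        kept, _ = filter_germline_panel([rec()], self.normals(1))
        assert len(kept) == 1

    def test_empty_panel_is_identity(self):
        records = [rec(), rec(pos=101)]
        kept, log = filter_germline_panel(records, self.normals(0).iloc[:0])
        assert kept == records and len(log) == 0


class TestDownsamplingFractions:
    def depths(self, rows):
        return pd.DataFrame(rows, columns=["exon_id", "cohort", "mean_depth"])

    def test_equal_depths_give_unit_fractions(self):
        f, excluded = compute_downsampling_fractions(
            self.depths([("e1", "A", 100.0), ("e1", "B", 100.0)])
        )
        assert (f["fraction"] == 1.0).all() and excluded == []

    def test_two_to_one_depth_halves_the_deeper_cohort(self):
        f, _ = compute_downsampling_fractions(
            self.depths([("e1", "A", 200.0), ("e1", "B", 100.0)])
        )
        by = f.set_index("cohort")["fraction"]
        assert by["A"] == pytest.approx(0.5)
        assert by["B"] == 1.0

    def test_deeper_cohort_loses_most_expected_reads(self):
        # three cohorts with Chinese at 2× depth: the expected read loss is
        # largest for the deep cohort (the directional downsampling effect)
        f, _ = compute_downsampling_fractions(
            self.depths(
                [("e1", "Caucasian", 80.0), ("e1", "Vietnamese", 85.0), ("e1", "Chinese", 160.0)]
            )
        )
        loss = {
            row.cohort: (1 - row.fraction)
            for row in f.itertuples()
        }
        assert loss["Chinese"] > loss["Vietnamese"] > loss["Caucasian"] == 0.0

    def test_exon_missing_in_a_cohort_flagged(self):
        f, excluded = compute_downsampling_fractions(
            self.depths([("e1", "A", 100.0), ("e1", "B", 90.0), ("e2", "A", 100.0)])
        )
        assert excluded == ["e2"]
        assert set(f["exon_id"]) == {"e1"}

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_downsampling_fractions(self.depths([("e1", "A", 0.0), ("e1", "B", 1.0)]))


class TestThinning:
    def counts(self, t_ref, t_alt, n=1):
        return pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "cohort": "A",
                "exon_id": "e1",
                "chrom": "1",
                "pos": 100,
                "ref": "C",
                "alt": "T",
                "t_ref": t_ref,
                "t_alt": t_alt,
                "n_ref": 30,
                "n_alt": 0,
            }
        )

    def fractions(self, f):
        return pd.DataFrame({"exon_id": ["e1"], "cohort": ["A"], "fraction": [f]})

    def test_fraction_one_is_identity(self):
        c = self.counts([90], [10])
        out = thin_counts(c, self.fractions(1.0), seed=0)
        pd.testing.assert_frame_equal(out, c)

    def test_zero_alt_stays_zero(self):
        out = thin_counts(self.counts([50], [0]), self.fractions(0.3), seed=1)
        assert out["t_alt"].iloc[0] == 0

    def test_binomial_moments_at_half(self):
        # thinning t_alt=100 at fraction 0.5 → mean ≈ 50, variance ≈ 25
        draws = [
            thin_counts(self.counts([0], [100]), self.fractions(0.5), seed=s)["t_alt"].iloc[0]
            for s in range(500)
        ]
        assert np.mean(draws) == pytest.approx(50, abs=3 * np.sqrt(25 / 500))
        assert np.var(draws) == pytest.approx(25, rel=0.35)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t_ref=st.integers(0, 500),
        t_alt=st.integers(0, 500),
        frac=st.floats(0.05, 1.0),
        seed=st.integers(0, 10_000),
    )
    def test_thinning_never_increases_counts(self, t_ref, t_alt, frac, seed):
        out = thin_counts(self.counts([t_ref], [t_alt]), self.fractions(frac), seed=seed)
        assert out["t_ref"].iloc[0] <= t_ref
        assert out["t_alt"].iloc[0] <= t_alt

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="fractions"):
            thin_counts(self.counts([10], [10]), self.fractions(0.0), seed=0)


class TestCaller:
    def test_zero_alt_not_called(self):
        assert call_site(100, 0) is False

    def test_worked_rule_evaluation(self):
        params = CallerParams(min_alt_reads=4, min_vaf=0.05, min_depth=20)
        assert call_site(90, 10, params=params) is True

    def test_depth_below_minimum_blocks_call(self):
        params = CallerParams(min_alt_reads=2, min_vaf=0.05, min_depth=20)
        assert call_site(5, 5, params=params) is False  # VAF 0.5 but depth 10

    def test_zero_depth_no_division_error(self):
        assert call_site(0, 0) is False

    def test_normal_contamination_blocks_call(self):
        params = CallerParams()
        assert call_site(60, 40, n_ref=50, n_alt=20, params=params) is False

    def test_invalid_min_vaf(self):
        with pytest.raises(ValueError):
            CallerParams(min_vaf=0.0)


class TestConsensus:
    def counts(self):
        return pd.DataFrame(
            {
                "sample_id": ["S1", "S2"],
                "cohort": ["A", "A"],
                "exon_id": ["e1", "e1"],
                "chrom": ["1", "1"],
                "pos": [100, 200],
                "ref": ["C", "C"],
                "alt": ["T", "T"],
                "t_ref": [60, 95],
                "t_alt": [40, 2],
                "n_ref": [50, 50],
                "n_alt": [0, 0],
            }
        )

    def unit_fractions(self):
        return pd.DataFrame({"exon_id": ["e1"], "cohort": ["A"], "fraction": [1.0]})

    def test_no_thinning_gives_all_or_nothing(self):
        out = consensus_calls(self.counts(), self.unit_fractions(), CallerParams(), base_seed=0)
        assert set(out["times_called"]) <= {10}
        assert out["consensus"].all()

    def test_strong_site_reaches_consensus_under_thinning(self):
        # expected post-thinning alt ≈ 20 ≫ thresholds → consensus w.h.p.
        fr = self.unit_fractions().assign(fraction=0.5)
        out = consensus_calls(self.counts(), fr, CallerParams(), base_seed=0)
        row = out[out["pos"] == 100]
        assert row["consensus"].all()

    def test_duplicate_seeds_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            consensus_calls(
                self.counts(), self.unit_fractions(), CallerParams(),
                n_iterations=3, min_times=2, seeds=[1, 1, 2],
            )

    def test_iterations_must_cover_min_times(self):
        with pytest.raises(ValueError):
            consensus_calls(
                self.counts(), self.unit_fractions(), CallerParams(),
                n_iterations=5, min_times=8,
            )


class TestValidationRate:
    def build(self, n_assessed, n_confirmed, n_shallow=3):
        pos = np.arange(n_assessed + n_shallow)
        wes = pd.DataFrame(
            {"sample_id": "S1", "chrom": "1", "pos": pos, "ref": "C", "alt": "T"}
        )
        targeted = wes.copy()
        targeted["depth"] = np.where(pos < n_assessed, 250, 50)
        targeted["called"] = pos < n_confirmed
        return wes, targeted

    def test_printed_counts_give_printed_rate(self):
        # 592 assessable WES calls of which 564 confirmed → 95.3%
        wes, targeted = self.build(592, 564)
        res = validation_rate(wes, targeted)
        assert (res.n_assessed, res.n_confirmed, res.rate_percent) == (592, 564, 95.3)

    def test_all_confirmed_is_hundred(self):
        wes, targeted = self.build(10, 10)
        assert validation_rate(wes, targeted).rate_percent == 100.0

    def test_disjoint_calls_zero(self):
        wes, targeted = self.build(10, 0)
        assert validation_rate(wes, targeted).rate_percent == 0.0

    def test_undefined_rate_raises(self):
        wes, targeted = self.build(0, 0, n_shallow=5)
        with pytest.raises(ValueError, match="undefined"):
            validation_rate(wes, targeted)


class TestDepthBalance:
    def test_realized_balance_after_targeted_thinning(self, default_data):
        counts = default_data.readcounts
        fractions, excluded = compute_downsampling_fractions(exon_depth_summary(counts))
        assert excluded == []
        thinned = thin_counts(counts, fractions, seed=11)
        report = depth_balance_report(thinned)
        assert report["std_diff_percent"].max() < 10.0

    def test_asymmetry_visible_before_thinning(self, default_data):
        report = depth_balance_report(default_data.readcounts)
        chinese = report[(report["cohort_a"] == "Chinese") | (report["cohort_b"] == "Chinese")]
        assert chinese["std_diff_percent"].median() > 10.0
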