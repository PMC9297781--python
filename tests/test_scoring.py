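"""Patient FS and variant VFS: estimator behaviour, thresholds, classification."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragmrd as fm
from fragmrd.fragio import SupportingFragments
from fragmrd.reference import FragmentScoreTable


def _flat_table(value: float, size: int = 601) -> FragmentScoreTable:
    scores = np.full(size, value)
    scores[0] = 0.0
    return FragmentScoreTable(scores=scores, meta={"cap": 5.0, "table_id": f"flat{value}"})


def _support(lengths, compartment="preop_plasma", patient="P1"):
    return SupportingFragments(
        patient_id=patient, compartment=compartment, chrom="chr1", pos=100,
        ref="A", alt="T", lengths=list(lengths),
    )


class TestPatientFS:
    def test_constant_score_pool_gives_that_constant(self):
        pool = fm.FragmentPool.from_lengths("p", [150, 160, 170] * 10, "patient_postop")
        res = fm.patient_fs(pool, _flat_table(2.5), n_sample=5000, seed=0)
        assert res.fs == pytest.approx(2.5)

    def test_matches_closed_form_expectation_within_monte_carlo_error(self, cohort, ref_table):
        pool = cohort.patients[0].postop
        exact = fm.expected_fs(pool, ref_table)
        p = pool.probabilities()
        s = ref_table.aligned(p.size)
        se = float(np.sqrt(p @ (s - exact) ** 2)) / np.sqrt(100_000)
        for seed in range(5):
            res = fm.patient_fs(pool, ref_table, n_sample=100_000, seed=seed)
            assert abs(res.fs - exact) < 3 * se

    def test_estimator_is_unbiased_over_seeds(self, cohort, ref_table):
        pool = cohort.patients[1].postop
        exact = fm.expected_fs(pool, ref_table)
        vals = [fm.patient_fs(pool, ref_table, n_sample=20_000, seed=s).fs for s in range(50)]
        p = pool.probabilities()
        s_vec = ref_table.aligned(p.size)
        se_mean = float(np.sqrt(p @ (s_vec - exact) ** 2)) / np.sqrt(20_000 * 50)
        assert abs(np.mean(vals) - exact) < 3 * se_mean

    def test_determinism_and_small_pool_with_replacement(self, ref_table):
        pool = fm.FragmentPool.from_lengths("tiny", [145, 167], "patient_postop")
        a = fm.patient_fs(pool, ref_table, n_sample=10_000, seed=3)
        b = fm.patient_fs(pool, ref_table, n_sample=10_000, seed=3)
        assert a.fs == b.fs  # with-replacement sampling works for pools < n_sample

    def test_empty_pool_errors(self, ref_table):
        with pytest.raises(ValueError, match="empty"):
            fm.patient_fs(fm.FragmentPool.from_lengths("e", []), ref_table)

    def test_replicate_ci_reports_both_spread_measures(self, cohort, ref_table):
        rep = fm.fs_replicates(cohort.patients[0].postop, ref_table,
                               n_replicates=5, n_sample=50_000, seed=0)
        assert rep["ci_low"] <= rep["mean"] <= rep["ci_high"]
        assert rep["range_width"] >= 0 and rep["ci_width"] > 0


class TestFsThreshold:
    def test_hand_computed_mean_plus_two_sd(self):
        assert fm.fs_threshold([-0.7, -0.6, -0.65]) == pytest.approx(-0.55)

    def test_identical_controls_give_their_value(self):
        assert fm.fs_threshold([-0.4, -0.4, -0.4]) == pytest.approx(-0.4)

    def test_too_few_controls(self):
        with pytest.raises(ValueError):
            fm.fs_threshold([-0.4])

    def test_call_is_strictly_greater_than(self):
        assert not fm.fs_call(1.0, 1.0)
        assert fm.fs_call(1.0 + 1e-12, 1.0)

    def test_control_distribution_false_positive_rate(self):
        """A sample from the control distribution exceeds mean+2SD rarely
        (Gaussian tail ~2.3%, inflated a little by threshold estimation noise)."""
        rng = np.random.default_rng(0)
        hits = 0
        trials = 2000
        for _ in range(trials):
            controls = rng.normal(-0.65, 0.05, size=15)
            test = rng.normal(-0.65, 0.05)
            hits += fm.fs_call(test, fm.fs_threshold(controls))
        assert hits / trials < 0.06

    def test_positivity_tracks_tumour_fraction(self, cohort, ref_table):
        rng = np.random.default_rng(1)
        ctrl_fs = [fm.patient_fs(c, ref_table, n_sample=200_000, seed=rng).fs
                   for c in cohort.controls]
        thr = fm.fs_threshold(ctrl_fs)
        truth = cohort.truth.set_index("patient_id")
        calls = {
            p.patient_id: fm.fs_call(
                fm.patient_fs(p.postop, ref_table, n_sample=200_000, seed=rng).fs, thr
            )
            for p in cohort.patients
        }
        high = [calls[pid] for pid in truth.index[truth["postop_tf"] >= 0.05]]
        zero = [calls[pid] for pid in truth.index[truth["postop_tf"] == 0.0]]
        assert np.mean(high) > np.mean(zero)


class TestVariantFS:
    def test_mean_over_supporting_fragments(self):
        table = FragmentScoreTable(scores=np.zeros(601), meta={"table_id": "t"})
        table.scores[140], table.scores[145] = 2.0, 3.0
        vfs = fm.variant_fs([_support([140, 145])], table)
        assert vfs.vfs == pytest.approx(2.5) and vfs.n_reads == 2

    def test_single_fragment_equals_per_fragment_score(self, ref_table):
        vfs = fm.variant_fs([_support([150])], ref_table)
        assert vfs.vfs == pytest.approx(float(ref_table.scores[150]))

    def test_all_fragments_one_length_equals_table_entry_exactly(self, ref_table):
        vfs = fm.variant_fs([_support([145] * 12)], ref_table)
        assert vfs.vfs == float(ref_table.scores[145])

    @given(
        pre=st.lists(st.integers(100, 400), min_size=1, max_size=20),
        post=st.lists(st.integers(100, 400), min_size=1, max_size=20),
    )
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_merged_vfs_is_count_weighted_mean_of_compartments(self, pre, post):
        table = _flat_table(0.0)
        table.scores[:] = np.sin(np.arange(table.scores.size))  # arbitrary fixed scores
        v_pre = fm.variant_fs([_support(pre, "preop_plasma")], table)
        v_post = fm.variant_fs([_support(post, "postop_plasma")], table)
        merged = fm.variant_fs(
            [_support(pre, "preop_plasma"), _support(post, "postop_plasma")], table
        )
        weighted = (v_pre.vfs * len(pre) + v_post.vfs * len(post)) / (len(pre) + len(post))
        assert merged.vfs == pytest.approx(weighted)
        assert merged.n_reads == len(pre) + len(post)

    def test_empty_support_is_indeterminate(self, ref_table):
        vfs = fm.variant_fs([_support([])], ref_table)
        assert np.isnan(vfs.vfs) and vfs.classification == "indeterminate"

    def test_mixed_variant_keys_rejected(self, ref_table):
        other = SupportingFragments("P1", "preop_plasma", "chr2", 5, "G", "C", [150])
        with pytest.raises(ValueError, match="multiple variants"):
            fm.variant_fs([_support([150]), other], ref_table)


class TestVfsNullThreshold:
    def test_n_equals_one_matches_pool_score_moments(self, pooled_nonmalignant, ref_table):
        p = pooled_nonmalignant.probabilities()
        s = ref_table.aligned(p.size)
        mean = p @ s
        sd = np.sqrt(p @ (s - mean) ** 2)
        thr = fm.vfs_null_threshold(pooled_nonmalignant, ref_table, n=1, n_iter=4000,
                                    rng=np.random.default_rng(0))
        assert thr == pytest.approx(mean + 2 * sd, rel=0.1)

    def test_large_n_limit_is_the_pool_mean_score(self, pooled_nonmalignant, ref_table):
        mean = fm.expected_fs(pooled_nonmalignant, ref_table)
        thr = fm.vfs_null_threshold(pooled_nonmalignant, ref_table, n=100_000,
                                    n_iter=200, rng=np.random.default_rng(0))
        assert thr == pytest.approx(mean, abs=0.02)

    def test_threshold_nonincreasing_in_expectation(self, pooled_nonmalignant, ref_table):
        ns = [2, 8, 32, 128]
        means = []
        for n in ns:
            vals = [
                fm.vfs_null_threshold(pooled_nonmalignant, ref_table, n=n, n_iter=300,
                                      rng=np.random.default_rng(100 + r))
                for r in range(5)
            ]
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))

    def test_n_iter_below_two_errors(self, pooled_nonmalignant, ref_table):
        with pytest.raises(ValueError):
            fm.vfs_null_threshold(pooled_nonmalignant, ref_table, n=5, n_iter=1)

    def test_cache_is_deterministic_and_keyed_by_table(self, pooled_nonmalignant, ref_table):
        thr_a = fm.VfsThresholds(pooled_nonmalignant, ref_table, n_iter=200, seed=1)
        thr_b = fm.VfsThresholds(pooled_nonmalignant, ref_table, n_iter=200, seed=1)
        assert thr_a(8) == thr_b(8)
        assert thr_a(8) == thr_a(8)  # cached value stable


class TestClassifyVariant:
    def test_below_eight_reads_is_indeterminate(self):
        rec = fm.VariantFS(key=("chr1", 1, "A", "T"), vfs=99.0, n_reads=7)
        assert fm.classify_variant(rec, lambda n: 0.0).classification == "indeterminate"

    def test_at_eight_reads_above_threshold_is_tumour(self):
        rec = fm.VariantFS(key=("chr1", 1, "A", "T"), vfs=1.0, n_reads=8)
        assert fm.classify_variant(rec, lambda n: 0.5).classification == "tumour"
        rec_low = fm.VariantFS(key=("chr1", 1, "A", "T"), vfs=0.4, n_reads=8)
        assert fm.classify_variant(rec_low, lambda n: 0.5).classification == "blood"

    def test_monotone_in_vfs_for_fixed_reads(self):
        order = {"blood": 0, "tumour": 1}
        labels = [
            fm.classify_variant(
                fm.VariantFS(key=("c", 1, "A", "T"), vfs=v, n_reads=10), lambda n: 0.0
            ).classification
            for v in np.linspace(-2, 2, 9)
        ]
        ranks = [order[l] for l in labels]
        assert ranks == sorted(ranks)

    def test_performance_score_arithmetic(self):
        cls = ["tumour", "tumour", "blood", "tumour", "indeterminate", "indeterminate"]
        truth = ["tumour", "tumour", "blood", "blood", "tumour", "blood"]
        assert fm.vfs_performance_score(cls, truth) == 2  # 3 right, 1 wrong, 2 skipped
        assert fm.vfs_performance_score(["indeterminate"] * 4, truth[:4]) == 0
        assert fm.vfs_performance_score(truth, truth) == len(truth)
        with pytest.raises(ValueError, match="mismatch"):
            fm.vfs_performance_score(cls[:2], truth)
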