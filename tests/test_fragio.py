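"""I/O round trips, schema validation and alignment extraction."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fragmrd as fm
from fragmrd.fragio import AlignmentError, ParseError

settings.register_profile("io", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("io")


# ---------------------------------------------------------------------------
# fragment pools
# ---------------------------------------------------------------------------


class TestFragmentPool:
    def test_histogram_is_lossless_and_total_is_cheap(self):
        pool = fm.FragmentPool.from_lengths("s1", [167, 167, 334, 140], "patient_preop")
        assert pool.total == 4
        assert pool.counts[167] == 2 and pool.counts[334] == 1
        assert list(pool.lengths()) == [140, 167, 167, 334]

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            fm.FragmentPool.from_lengths("s1", [167, 0])

    def test_rejects_unknown_source_label(self):
        with pytest.raises(ValueError, match="source_label"):
            fm.FragmentPool.from_lengths("s1", [167], source_label="serum")

    def test_probabilities_error_on_empty_pool(self):
        pool = fm.FragmentPool.from_lengths("s1", [])
        with pytest.raises(ValueError, match="empty"):
            pool.probabilities()

    def test_merge_pools_adds_histograms(self):
        a = fm.FragmentPool.from_lengths("a", [100, 100])
        b = fm.FragmentPool.from_lengths("b", [100, 200])
        merged = fm.merge_pools([a, b], "ab", "nonmalignant")
        assert merged.counts[100] == 3 and merged.counts[200] == 1


# ---------------------------------------------------------------------------
# fragment tables
# ---------------------------------------------------------------------------


class TestFragmentTable:
    def test_repeated_length_rows_are_summed(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("sample_id\tlength\tcount\ns1\t167\t10\ns1\t167\t5\n")
        pool = fm.read_fragment_table(path)
        assert pool.counts[167] == 15 and pool.total == 15

    def test_empty_body_gives_empty_pool(self, tmp_path, caplog):
        path = tmp_path / "f.tsv"
        path.write_text("sample_id\tlength\tcount\n")
        with caplog.at_level("WARNING"):
            pool = fm.read_fragment_table(path)
        assert pool.total == 0
        assert any("empty" in r.message or "no data" in r.message for r in caplog.records)

    @pytest.mark.parametrize(
        "body, message",
        [
            ("s1\t167\t-2\n", "negative count"),
            ("s1\t16.5\t3\n", "non-integer"),
            ("s1\t0\t3\n", "length must be >= 1"),
        ],
    )
    def test_bad_rows_are_fatal_with_line_number(self, tmp_path, body, message):
        path = tmp_path / "f.tsv"
        path.write_text("sample_id\tlength\tcount\n" + body)
        with pytest.raises(ParseError, match="line 2"):
            fm.read_fragment_table(path)

    @given(lengths=st.lists(st.integers(min_value=1, max_value=600), min_size=1, max_size=50))
    def test_write_read_round_trip(self, tmp_path_factory, lengths):
        pool = fm.FragmentPool.from_lengths("s1", lengths, "patient_postop")
        path = tmp_path_factory.mktemp("rt") / "f.tsv"
        fm.write_fragment_table(pool, path)
        back = fm.read_fragment_table(path, source_label="patient_postop")
        assert np.array_equal(back.padded(pool.counts.size), pool.counts)

    def test_multi_sample_table(self, tmp_path):
        a = fm.FragmentPool.from_lengths("a", [150])
        b = fm.FragmentPool.from_lengths("b", [160])
        path = tmp_path / "f.tsv"
        fm.write_fragment_table([a, b], path)
        pools = fm.read_fragment_tables(path)
        assert set(pools) == {"a", "b"}
        with pytest.raises(ParseError, match="one sample"):
            fm.read_fragment_table(path)


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

_VHEADER = "patient_id\tcompartment\tchrom\tpos\tref\talt\talt_reads\tdepth\tpipeline_called\n"


class TestVariantTable:
    def test_valid_row(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(_VHEADER + "P01\ttissue\tchr1\t100\tA\tT\t5\t100\ttrue\n")
        (obs,) = fm.read_variant_table(path)
        assert obs.key == ("chr1", 100, "A", "T") and obs.pipeline_called

    def test_unknown_compartment_names_allowed_values(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(_VHEADER + "P01\tserum\tchr1\t100\tA\tT\t5\t100\ttrue\n")
        with pytest.raises(ParseError, match="preop_plasma"):
            fm.read_variant_table(path)

    def test_alt_reads_exceeding_depth_is_fatal(self, tmp_path):
        path = tmp_path / "v.tsv"
        path.write_text(_VHEADER + "P01\ttissue\tchr1\t100\tA\tT\t101\t100\ttrue\n")
        with pytest.raises(ParseError, match="exceeds depth"):
            fm.read_variant_table(path)

    def test_round_trip(self, tmp_path, cohort):
        observations = [o for p in cohort.patients[:3] for o in p.observations]
        path = tmp_path / "v.tsv"
        fm.write_variant_table(observations, path)
        assert fm.read_variant_table(path) == observations


class TestSupportingFragments:
    def test_round_trip_preserves_grouping(self, tmp_path, cohort):
        records = [s for p in cohort.patients[:3] for s in p.support]
        path = tmp_path / "s.tsv"
        fm.write_supporting_fragments(records, path)
        back = fm.read_supporting_fragments(path)
        assert [(r.patient_id, r.compartment, r.key, r.lengths) for r in back] == [
            (r.patient_id, r.compartment, r.key, r.lengths) for r in records
        ]


class TestScoreTable:
    def test_round_trip_with_metadata_sidecar(self, tmp_path, ref_table):
        path = tmp_path / "table.tsv"
        fm.write_score_table(ref_table, path)
        back = fm.read_score_table(path)
        np.testing.assert_allclose(
            back.scores[: ref_table.scores.size], ref_table.scores, atol=1e-9
        )
        assert back.meta["n_boot"] == ref_table.meta["n_boot"]
        assert back.table_id == ref_table.table_id


# ---------------------------------------------------------------------------
# alignment extraction
# ---------------------------------------------------------------------------

_SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def _pair(name: str, tlen: int, flag1: int = 99, flag2: int = 147, mapq: int = 60) -> str:
    pos = 1000
    return (
        f"{name}\t{flag1}\tchr1\t{pos}\t{mapq}\t50M\t=\t{pos + abs(tlen) - 50}\t{abs(tlen)}\t*\t*\n"
        f"{name}\t{flag2}\tchr1\t{pos + abs(tlen) - 50}\t{mapq}\t50M\t=\t{pos}\t{-abs(tlen)}\t*\t*\n"
    )


class TestAlignmentExtraction:
    def test_one_length_per_pair_absolute_template_length(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(_SAM_HEADER + _pair("a", 167) + _pair("b", 334) + _pair("c", 140))
        pool = fm.read_fragment_lengths_from_alignment(sam)
        assert sorted(pool.lengths()) == [140, 167, 334]

    def test_duplicate_flagged_pair_contributes_nothing(self, tmp_path):
        sam = tmp_path / "dup.sam"
        # 0x400 duplicate flag set on both mates
        sam.write_text(_SAM_HEADER + _pair("a", 167, flag1=99 | 1024, flag2=147 | 1024))
        pool = fm.read_fragment_lengths_from_alignment(sam)
        assert pool.total == 0

    def test_low_mapq_and_overlong_fragments_are_discarded(self, tmp_path):
        sam = tmp_path / "filt.sam"
        sam.write_text(_SAM_HEADER + _pair("a", 167, mapq=5) + _pair("b", 700))
        pool = fm.read_fragment_lengths_from_alignment(sam, min_mapq=20, length_cap=600)
        assert pool.total == 0

    def test_single_end_data_is_fatal(self, tmp_path):
        sam = tmp_path / "se.sam"
        sam.write_text(_SAM_HEADER + "a\t0\tchr1\t1000\t60\t50M\t*\t0\t0\t*\t*\n")
        with pytest.raises(AlignmentError, match="paired-end"):
            fm.read_fragment_lengths_from_alignment(sam)

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(AlignmentError, match="not found"):
            fm.read_fragment_lengths_from_alignment(tmp_path / "nope.sam")

    def test_round_trip_through_alignment_writer(self, tmp_path):
        rng = np.random.default_rng(7)
        pool = fm.FragmentPool.from_lengths(
            "rt", rng.integers(80, 500, size=200), "patient_postop"
        )
        sam = tmp_path / "rt.sam"
        fm.write_fragment_alignment(pool, sam)
        back = fm.read_fragment_lengths_from_alignment(sam, sample_id="rt")
        assert np.array_equal(back.padded(pool.counts.size), pool.counts)

    def test_alignment_and_tsv_ingestion_agree(self, tmp_path):
        pool = fm.sample_fragment_pool(fm.NONTUMOUR_PROFILE, 300, seed=3, sample_id="x")
        sam, tsv = tmp_path / "x.sam", tmp_path / "x.tsv"
        fm.write_fragment_alignment(pool, sam)
        fm.write_fragment_table(pool, tsv)
        from_sam = fm.read_fragment_lengths_from_alignment(sam)
        from_tsv = fm.read_fragment_table(tsv)
        assert np.array_equal(
            from_sam.padded(from_tsv.counts.size), from_tsv.padded(from_sam.counts.size)
        )


# ---------------------------------------------------------------------------
# cohort directory
# ---------------------------------------------------------------------------


def test_cohort_directory_round_trip(tmp_path, cohort):
    fm.write_cohort(cohort, tmp_path / "cohort")
    patients, controls, meta = fm.read_cohort(tmp_path / "cohort")
    assert [p.patient_id for p in patients] == [p.patient_id for p in cohort.patients]
    assert len(controls) == len(cohort.controls)
    orig = cohort.patients[0]
    back = patients[0]
    assert back.recurrence == orig.recurrence
    assert back.observations == orig.observations
    assert np.array_equal(back.postop.padded(orig.postop.counts.size), orig.postop.counts)
    assert np.array_equal(
        back.tumour_fragments.padded(orig.tumour_fragments.counts.size),
        orig.tumour_fragments.counts,
    )
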