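"""Tests of the TSS relative-coverage statistic and matrix construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfdna_tss import (
    CoverageMatrix,
    DepthWindow,
    ReadFilterSpec,
    TssAnnotation,
    build_coverage_matrix,
    read_fragments,
    tss_relative_coverage,
)
from conftest import naive_relative_coverage


def make_annotation(positions, chrom="chr1", genes=None):
    n = len(positions)
    return TssAnnotation(
        pd.DataFrame(
            {
                "chrom": chrom,
                "tss_pos": positions,
                "strand": ["+"] * n,
                "transcript_id": [f"T{i}" for i in range(n)],
                "gene_symbol": genes or [f"G{i}" for i in range(n)],
            }
        )
    )


def frame(intervals, chrom="chr1"):
    return pd.DataFrame(
        {"chrom": chrom, "start": [a for a, _ in intervals], "end": [b for _, b in intervals]}
    )


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------


class TestStatistic:
    def test_uniform_depth_is_exactly_one(self):
        w = DepthWindow(np.full(1000, 3.0), np.full(1000, 3.0), np.full(1000, 3.0))
        assert tss_relative_coverage(w) == 1.0

    def test_full_central_depletion_is_zero(self):
        w = DepthWindow(np.zeros(1000), np.full(1000, 2.0), np.full(1000, 2.0))
        assert tss_relative_coverage(w) == 0.0

    def test_asymmetric_flanks_brute_force(self):
        central = np.full(1000, 5.0)
        left, right = np.full(1000, 8.0), np.full(1000, 12.0)
        expected = (central.sum() / 1000) / ((left.sum() + right.sum()) / 2000)
        assert expected == 0.5  # independent base-by-base summation
        assert tss_relative_coverage(DepthWindow(central, left, right)) == expected

    def test_zero_background_is_masked_not_error(self):
        w = DepthWindow(np.ones(1000), np.zeros(1000), np.zeros(1000))
        assert np.isnan(tss_relative_coverage(w))

    @given(
        depths=st.lists(st.floats(0.1, 50.0), min_size=3, max_size=3),
        k=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, depths, k):
        c, l, r = depths
        base = tss_relative_coverage(
            DepthWindow(np.full(1000, c), np.full(1000, l), np.full(1000, r))
        )
        scaled = tss_relative_coverage(
            DepthWindow(np.full(1000, c * k), np.full(1000, l * k), np.full(1000, r * k))
        )
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_window_length_enforced(self):
        with pytest.raises(ValueError, match="1000"):
            DepthWindow(np.ones(1001), np.ones(1000), np.ones(1000))


# ---------------------------------------------------------------------------
# matrix construction
# ---------------------------------------------------------------------------


class TestMatrix:
    def test_single_spanning_fragment_gives_one(self):
        ann = make_annotation([5000])
        frags = frame([(3500, 6500)])  # uniform depth 1 across all three windows
        m = build_coverage_matrix({"s1": frags}, ann)
        assert m.values.loc["s1", "T0"] == 1.0

    def test_central_only_fragment_is_masked(self):
        ann = make_annotation([5000])
        frags = frame([(4500, 5500)])  # covers exactly the central window
        m = build_coverage_matrix({"s1": frags}, ann)
        assert m.mask.loc["s1", "T0"]
        assert np.isnan(m.values.loc["s1", "T0"])

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        positions = [2000, 6000, 11000, 15500, 20000]
        ann = make_annotation(positions)
        starts = rng.integers(0, 21000, size=50)
        lengths = rng.integers(50, 400, size=50)
        frags = frame(list(zip(starts, starts + lengths)))
        m = build_coverage_matrix({"s1": frags}, ann)
        for tid, pos in zip(ann.table["transcript_id"], positions):
            expected = naive_relative_coverage(frags, "chr1", pos)
            got = m.values.loc["s1", tid]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_fragment_replication_scale_invariance(self):
        rng = np.random.default_rng(0)
        ann = make_annotation([4000, 9000])
        starts = rng.integers(0, 10000, size=30)
        frags = frame(list(zip(starts, starts + 167)))
        m1 = build_coverage_matrix({"s1": frags}, ann)
        tripled = pd.concat([frags] * 3, ignore_index=True)
        m3 = build_coverage_matrix({"s1": tripled}, ann)
        pd.testing.assert_frame_equal(m1.values, m3.values)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        starts = rng.integers(0, 8000, size=40)
        frags = frame(list(zip(starts, starts + 160)))
        ann_plus = make_annotation([4000])
        ann_minus = make_annotation([4000])
        ann_minus.table["strand"] = "-"
        m_plus = build_coverage_matrix({"s1": frags}, ann_plus)
        m_minus = build_coverage_matrix({"s1": frags}, ann_minus)
        pd.testing.assert_frame_equal(m_plus.values, m_minus.values)

    def test_sample_order_equivariance(self):
        rng = np.random.default_rng(2)
        ann = make_annotation([4000])
        mk = lambda seed: frame(
            [(s, s + 150) for s in np.random.default_rng(seed).integers(0, 8000, 30)]
        )
        a, b = mk(10), mk(11)
        m_ab = build_coverage_matrix([("a", a), ("b", b)], ann)
        m_ba = build_coverage_matrix([("b", b), ("a", a)], ann)
        pd.testing.assert_frame_equal(m_ab.values, m_ba.values.loc[["a", "b"]])

    def test_duplicate_tss_coordinates_share_value(self):
        ann = TssAnnotation(
            pd.DataFrame(
                {
                    "chrom": ["chr1", "chr1"],
                    "tss_pos": [4000, 4000],
                    "strand": ["+", "-"],
                    "transcript_id": ["Ta", "Tb"],
                    "gene_symbol": ["G1", "G2"],
                }
            )
        )
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 8000, size=60)
        m = build_coverage_matrix({"s1": frame(list(zip(starts, starts + 150)))}, ann)
        assert m.values.loc["s1", "Ta"] == m.values.loc["s1", "Tb"]

    def test_unusable_tss_masked(self):
        ann = make_annotation([800, 5000])  # first site lacks a full left flank
        starts = np.arange(0, 8000, 100)
        m = build_coverage_matrix({"s1": frame(list(zip(starts, starts + 150)))}, ann)
        assert m.mask.loc["s1", "T0"]
        assert not m.mask.loc["s1", "T1"]

    def test_errors(self):
        ann = make_annotation([5000])
        with pytest.raises(ValueError, match="no fragments"):
            build_coverage_matrix({"s1": frame([])}, ann)
        with pytest.raises(ValueError, match="usable"):
            build_coverage_matrix({"s1": frame([(0, 100)])}, make_annotation([100]))

    def test_tsv_roundtrip(self, tmp_path):
        ann = make_annotation([5000])
        m = build_coverage_matrix({"s1": frame([(3500, 6500)])}, ann)
        p = tmp_path / "m.tsv"
        m.to_tsv(p, tmp_path / "mask.tsv")
        back = CoverageMatrix.from_tsv(p)
        pd.testing.assert_frame_equal(m.values, back.values)


# ---------------------------------------------------------------------------
# annotation and fragment input
# ---------------------------------------------------------------------------


class TestAnnotation:
    def test_bed_roundtrip(self, tmp_path):
        ann = make_annotation([2000, 6000], genes=["GA", "GB"])
        p = tmp_path / "tss.bed"
        ann.to_bed(p)
        back = TssAnnotation.from_bed(p)
        pd.testing.assert_frame_equal(ann.table, back.table)

    def test_duplicate_transcript_ids_rejected(self):
        df = make_annotation([2000, 6000]).table
        df["transcript_id"] = "T0"
        with pytest.raises(ValueError, match="duplicate"):
            TssAnnotation(df)


def _write_bam(path, records, sorted_by="coordinate"):
    """records: (pos, mapq, flag, tlen) on a 50kb contig; flag 99/147-style pairs."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": sorted_by}, "SQ": [{"SN": "chr1", "LN": 50000}]}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for i, (pos, mapq, flag, tlen) in enumerate(sorted(records)):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = f"r{i}"
            a.reference_name = "chr1"
            a.reference_start = pos
            a.mapping_quality = mapq
            a.flag = flag
            a.query_sequence = "A" * 50
            a.cigarstring = "50M"
            a.next_reference_name = "chr1"
            a.next_reference_start = pos + max(tlen, 0)
            a.template_length = tlen
            bam.write(a)
    pysam.index(str(path))


class TestReadFragments:
    def test_bed_passthrough(self, tmp_path):
        p = tmp_path / "f.bed"
        frame([(10, 180), (300, 460)]).to_csv(p, sep="\t", header=False, index=False)
        out = read_fragments(p)
        assert list(out["start"]) == [10, 300]

    def test_duplicate_flag_excluded(self, tmp_path):
        p = tmp_path / "dup.bam"
        _write_bam(p, [(100, 60, 99 | 1024, 200), (250, 60, 147 | 1024, -200)])
        assert len(read_fragments(p)) == 0

    def test_mapq_threshold(self, tmp_path):
        low = tmp_path / "low.bam"
        _write_bam(low, [(100, 1, 99, 200), (250, 1, 147, -200)])
        assert len(read_fragments(low)) == 0
        ok = tmp_path / "ok.bam"
        _write_bam(ok, [(100, 2, 99, 200), (250, 2, 147, -200)])
        frags = read_fragments(ok)
        assert len(frags) == 1
        assert (frags.loc[0, "start"], frags.loc[0, "end"]) == (100, 300)

    def test_mixed_flags_match_per_record_tally(self, tmp_path):
        records = [
            (100, 60, 99, 200), (250, 60, 147, -200),       # clean pair
            (400, 60, 99 | 256, 200), (550, 60, 147 | 256, -200),   # secondary
            (700, 60, 99 | 512, 200), (850, 60, 147 | 512, -200),   # qc-fail
            (1000, 1, 99, 200), (1150, 1, 147, -200),       # low mapq
            (1300, 30, 99 | 2048, 200), (1450, 30, 147, -200),  # supplementary r1
        ]
        spec = ReadFilterSpec()
        # independent flag-by-flag tally of leftmost mates surviving the filters
        expected = sum(
            1
            for pos, mapq, flag, tlen in records
            if tlen > 0 and not (flag & spec.flag_mask) and mapq >= spec.min_mapq
        )
        p = tmp_path / "mix.bam"
        _write_bam(p, records)
        assert len(read_fragments(p, spec)) == expected == 1

    def test_unsorted_bam_rejected_with_remedy(self, tmp_path):
        import pysam

        p = tmp_path / "unsorted.bam"
        header = {"HD": {"VN": "1.6", "SO": "queryname"}, "SQ": [{"SN": "chr1", "LN": 50000}]}
        with pysam.AlignmentFile(p, "wb", header=header) as bam:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = "r0"
            a.reference_name = "chr1"
            a.reference_start = 10
            a.mapping_quality = 60
            a.flag = 0
            a.query_sequence = "A" * 50
            a.cigarstring = "50M"
            bam.write(a)
        with pytest.raises(ValueError, match="sort|index"):
            read_fragments(p)

    def test_unknown_extension_rejected(self, tmp_path):
        p = tmp_path / "frags.txt"
        p.write_text("chr1\t1\t2\n")
        with pytest.raises(ValueError, match="extension"):
            read_fragments(p)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_fragments("/nonexistent/x.bed")
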