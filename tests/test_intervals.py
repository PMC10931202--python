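"""Interval model, set algebra and BED/narrowPeak I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rosette.intervals import (
    GenomicInterval,
    IntervalSet,
    PeakParseError,
    cluster_intervals,
    intersect_sets,
    jaccard_bp,
    merge_adjacent,
    overlap_length,
    overlaps,
    read_peaks,
    write_bed,
)

from _oracles import (
    allpairs_overlap_pairs,
    bitmap_merged_intervals,
    bitmap_union_bases,
    random_intervals,
    unionfind_merge,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 10)

    def test_length_and_center_follow_half_open_convention(self):
        iv = GenomicInterval("chr1", 100, 201)
        assert len(iv) == 101
        assert iv.center == 150


class TestOverlaps:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            # one shared base at the boundary
            (("chr1", 100, 200), ("chr1", 199, 300), True),
            # book-ended: zero shared bases under half-open coordinates
            (("chr1", 100, 200), ("chr1", 200, 300), False),
            (("chr1", 100, 200), ("chr2", 100, 200), False),
            (("chr1", 100, 200), ("chr1", 50, 101), True),
        ],
    )
    def test_one_bp_rule(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected

    def test_min_bp_threshold(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 90, 200)
        assert overlaps(a, b, min_bp=10)
        assert not overlaps(a, b, min_bp=11)

    @given(
        s1=st.integers(0, 500), w1=st.integers(1, 200),
        s2=st.integers(0, 500), w2=st.integers(1, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_overlap_is_symmetric(self, s1, w1, s2, w2):
        a = GenomicInterval("chr1", s1, s1 + w1)
        b = GenomicInterval("chr1", s2, s2 + w2)
        assert overlaps(a, b) == overlaps(b, a)
        assert overlap_length(a, b) == overlap_length(b, a)


class TestIO:
    def test_bed_line_maps_fields(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tpk1\t7\n")
        (iv,) = read_peaks(p)
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.score) == ("chr1", 100, 200, "pk1", 7.0)

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_peaks(p)) == 0

    def test_unsorted_input_is_sorted(self, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text("chr2\t5\t10\nchr1\t50\t60\nchr1\t5\t10\n")
        got = [(iv.chrom, iv.start) for iv in read_peaks(p)]
        assert got == sorted(got)  # lexicographic chrom, then numeric start

    def test_narrowpeak_score_from_signal_value(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t10\t50\tpk\t900\t.\t13.5\t40.2\t38.1\t20\n")
        (iv,) = read_peaks(p, format="narrowPeak")
        assert iv.score == 13.5

    def test_narrowpeak_requires_ten_fields(self, tmp_path):
        p = tmp_path / "b.narrowPeak"
        p.write_text("chr1\t10\t50\n")
        with pytest.raises(PeakParseError, match="line 1"):
            read_peaks(p, format="narrowPeak")

    @pytest.mark.parametrize(
        "line", ["chr1\t200\t100", "chr1\tx\t100", "chr1\t5"]
    )
    def test_malformed_lines_name_the_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(PeakParseError, match="line 2"):
            read_peaks(p)

    def test_unknown_format_token(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1\t2\n")
        with pytest.raises(ValueError, match="format"):
            read_peaks(p, format="gff")

    def test_round_trip_preserves_coordinates_and_scores(self, tmp_path, rng):
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(w), name=f"p{i}", score=float(i) / 3)
            for i, (s, w) in enumerate(zip(rng.integers(0, 10_000, 50), rng.integers(1, 500, 50)))
        ]
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        back = read_peaks(p)
        expect = sorted(ivs, key=GenomicInterval.sort_key)
        assert [(iv.chrom, iv.start, iv.end, iv.score) for iv in back] == [
            (iv.chrom, iv.start, iv.end, iv.score) for iv in expect
        ]

    def test_genome_table_bounds_enforced(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t5000\n")
        with pytest.raises(ValueError, match="extends past"):
            read_peaks(p, genome={"chr1": 1000})


class TestIntersectSets:
    def test_identical_sets_fully_overlap(self, rng):
        s = IntervalSet(random_intervals(rng, 30))
        res = intersect_sets(s, s)
        assert res.a_overlapping == len(s) and res.b_overlapping == len(s)
        assert res.a_only == 0 and res.b_only == 0

    def test_empty_other_set(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        res = intersect_sets(a, IntervalSet())
        assert res.a_only == 1 and res.a_overlapping == 0 and res.n_pairs == 0

    def test_counts_match_allpairs_oracle(self, rng):
        a = IntervalSet(random_intervals(rng, 200, length=100_000))
        b = IntervalSet(random_intervals(rng, 200, length=100_000))
        res = intersect_sets(a, b)
        oracle = allpairs_overlap_pairs(list(a), list(b))
        assert len(res.pairs) == len(oracle)
        assert res.a_overlapping == len({i for i, _ in oracle})
        assert res.b_overlapping == len({j for _, j in oracle})


class TestMergeAdjacent:
    def test_stitch_distance_example(self):
        s = IntervalSet(
            [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 12_900, 13_400)]
        )
        merged = merge_adjacent(s, 12_500)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 13_400)]
        # just past the threshold: two regions
        far = IntervalSet(
            [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 13_001, 13_400)]
        )
        assert len(merge_adjacent(far, 12_500)) == 2

    def test_single_interval_unchanged(self):
        s = IntervalSet([GenomicInterval("chr1", 5, 10)])
        assert merge_adjacent(s, 1000) == s

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            merge_adjacent(IntervalSet(), -1)

    def test_matches_unionfind_oracle(self, rng):
        ivs = random_intervals(rng, 100, length=50_000, max_width=1_500)
        got = list(merge_adjacent(IntervalSet(ivs), 1000))
        expect = unionfind_merge(ivs, 1000)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == [
            (iv.chrom, iv.start, iv.end) for iv in expect
        ]

    def test_gap_zero_equals_bitmap_union(self, rng):
        lengths = {"chrA": 100_000, "chrB": 100_000}
        ivs = random_intervals(rng, 150, length=100_000)
        merged = merge_adjacent(IntervalSet(ivs), 0)
        assert sum(len(iv) for iv in merged) == bitmap_union_bases(ivs, lengths)
        assert [(iv.chrom, iv.start, iv.end) for iv in merged] == [
            (iv.chrom, iv.start, iv.end) for iv in bitmap_merged_intervals(ivs, lengths)
        ]

    @pytest.mark.parametrize("gap", [0, 100, 12_500])
    def test_idempotent(self, rng, gap):
        s = IntervalSet(random_intervals(rng, 80))
        once = merge_adjacent(s, gap)
        assert merge_adjacent(once, gap) == once

    def test_constituents_recorded(self):
        ivs = [
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 150, 250),
            GenomicInterval("chr1", 10_000, 10_100),
        ]
        out = merge_adjacent(IntervalSet(ivs), 100, return_constituents=True)
        assert [len(members) for _, members in out] == [2, 1]
        span, members = out[0]
        assert (span.start, span.end) == (0, 250)
        assert all(span.start <= m.start and m.end <= span.end for m in members)


class TestClusterIntervals:
    def test_strict_overlap_vs_bookended(self):
        ivs = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)]
        assert len(cluster_intervals(ivs, max_gap=-1)) == 2  # touching only
        assert len(cluster_intervals(ivs, max_gap=0)) == 1


class TestJaccard:
    def test_identical_sets_give_one(self, rng):
        s = IntervalSet(random_intervals(rng, 20))
        assert jaccard_bp(s, s) == pytest.approx(1.0)

    def test_disjoint_sets_give_zero(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 20, 30)])
        assert jaccard_bp(a, b) == 0.0

    def test_half_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 50, 150)])
        assert jaccard_bp(a, b) == pytest.approx(50 / 150)
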