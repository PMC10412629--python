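"""Interval algebra, tiling, signal arithmetic and BED I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from k9dyn.intervals import (
    GenomicInterval,
    IntervalSet,
    base_coverage_fraction,
    marked_fraction,
    merge_intervals,
    overlap_marked,
    promoters_from_tss,
    read_bed,
    rpkm,
    tile_windows,
    window_signal,
    write_bed,
)

from conftest import brute_covered_positions, brute_overlap_marked, random_interval_set


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 50)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 50)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 50)

    def test_length(self):
        assert len(GenomicInterval("chr1", 10, 25)) == 15


class TestBedIO:
    def test_roundtrip_and_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("# comment\ntrack name=x\nchr1\t0\t1000\nchr2\t5\t10\tpk\t3.5\t+\n")
        s = read_bed(p)
        assert [(iv.chrom, iv.start, iv.end) for iv in s] == [
            ("chr1", 0, 1000),
            ("chr2", 5, 10),
        ]
        assert s[1].name == "pk" and s[1].score == 3.5 and s[1].strand == "+"
        out = tmp_path / "b.bed"
        write_bed(s, out)
        assert read_bed(out) == s

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    @pytest.mark.parametrize(
        "line", ["chr1\t100\t50", "chr1\tx\t50", "chr1\t100"]
    )
    def test_malformed_line_names_lineno(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p)


class TestMerge:
    @pytest.mark.parametrize(
        "ivs,expected",
        [
            ([(0, 10), (5, 20)], [(0, 20)]),
            ([(0, 10), (10, 20)], [(0, 20)]),  # touching intervals merge
            ([(0, 10), (15, 20)], [(0, 10), (15, 20)]),
        ],
    )
    def test_basic(self, ivs, expected):
        s = IntervalSet([GenomicInterval("chr1", a, b) for a, b in ivs])
        got = [(iv.start, iv.end) for iv in merge_intervals(s)]
        assert got == expected

    def test_per_base_oracle_and_idempotence(self, rng):
        s = random_interval_set(rng, 1000)
        m = merge_intervals(s)
        assert brute_covered_positions(m) == brute_covered_positions(s)
        assert merge_intervals(m) == m
        # merged set is sorted and pairwise disjoint
        for a, b in zip(m, m.intervals[1:]):
            assert (a.chrom, a.start) <= (b.chrom, b.start)
            assert a.chrom != b.chrom or a.end < b.start


class TestTileWindows:
    def test_exact_and_remainder(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 2500)])
        tiles = [(w.start, w.end) for w in tile_windows(s)]
        assert tiles == [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_base_conservation_on_random_merged_set(self, rng):
        s = merge_intervals(random_interval_set(rng, 300))
        tiles = tile_windows(s, 137)
        assert tiles.total_bases() == s.total_bases()
        assert brute_covered_positions(tiles) == brute_covered_positions(s)

    def test_bad_width(self):
        with pytest.raises(ValueError):
            tile_windows(IntervalSet(), 0)


class TestSignalArithmetic:
    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(10, 1000, 1e6, 10.0), (0, 1000, 1e6, 0.0), (7, 500, 2e6, 7.0)],
    )
    def test_rpkm(self, count, length, lib, expected):
        assert rpkm(count, length, lib) == pytest.approx(expected)

    def test_rpkm_errors(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_window_signal_scalars(self):
        assert window_signal(5.0, 5.0) == 0.0
        assert window_signal(3.0, 1.0) == pytest.approx(1.0)  # log2(4/2)

    def test_window_signal_matrix_matches_scalar_loop(self, rng):
        chip = rng.uniform(0, 20, size=(6, 4))
        inp = rng.uniform(0, 20, size=(6, 4))
        mat = window_signal(chip, inp, pseudocount=0.5)
        for i in range(6):
            for j in range(4):
                assert mat[i, j] == pytest.approx(
                    math.log2((chip[i, j] + 0.5) / (inp[i, j] + 0.5))
                )


class TestOverlapMarked:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 1000), (0, 1000), True),       # identity
            ((0, 1000), (900, 5000), False),    # 100 < 500 and < 2050
            ((0, 1000), (400, 600), True),      # covers half of b
        ],
    )
    def test_pairs(self, a, b, expected):
        av = GenomicInterval("chr1", *a)
        bs = IntervalSet([GenomicInterval("chr1", *b)])
        assert overlap_marked(av, bs) is expected

    def test_agrees_with_brute_force(self, rng):
        peaks = random_interval_set(rng, 200)
        merged = merge_intervals(peaks)
        for a in random_interval_set(rng, 200):
            assert overlap_marked(a, merged) == brute_overlap_marked(a, merged)

    def test_reciprocal_symmetry(self, rng):
        """The -e disjunction gives the same answer regardless of which
        interval of a pair plays the query role."""
        for _ in range(100):
            s1 = int(rng.integers(0, 5000))
            s2 = int(rng.integers(0, 5000))
            a = GenomicInterval("chr1", s1, s1 + int(rng.integers(1, 800)))
            b = GenomicInterval("chr1", s2, s2 + int(rng.integers(1, 800)))
            assert overlap_marked(a, IntervalSet([b])) == overlap_marked(
                b, IntervalSet([a])
            )


class TestMarkedFraction:
    def test_basic(self):
        regions = IntervalSet(
            [GenomicInterval("chr1", 0, 1000), GenomicInterval("chr1", 2000, 3000)]
        )
        peaks = IntervalSet([GenomicInterval("chr1", 0, 600)])
        assert marked_fraction(regions, peaks) == 0.5
        assert marked_fraction(regions, IntervalSet()) == 0.0

    def test_empty_regions_error(self):
        with pytest.raises(ValueError):
            marked_fraction(IntervalSet(), IntervalSet())

    def test_monotone_under_peak_union(self, rng):
        regions = random_interval_set(rng, 80)
        p1 = random_interval_set(rng, 40)
        p2 = IntervalSet(p1.intervals + random_interval_set(rng, 40).intervals)
        assert marked_fraction(regions, p2) >= marked_fraction(regions, p1)

    def test_base_level_variant(self):
        regions = IntervalSet([GenomicInterval("chr1", 0, 1000)])
        peaks = IntervalSet([GenomicInterval("chr1", 0, 250)])
        assert base_coverage_fraction(regions, peaks) == 0.25


class TestPromoters:
    def test_flank_and_clipping(self):
        s = promoters_from_tss([("chr1", 5000, "+"), ("chr1", 500, "-")])
        assert (s[0].start, s[0].end) == (4000, 6000)
        assert (s[1].start, s[1].end) == (0, 1500)

    @given(st.lists(st.integers(min_value=0, max_value=10**8), min_size=1, max_size=50))
    @settings(deadline=None)
    def test_batch_properties(self, positions):
        s = promoters_from_tss([("chrX", p, ".") for p in positions])
        assert len(s) == len(positions)
        assert all(len(iv) <= 2000 for iv in s)
        assert all(iv.start >= 0 for iv in s)


@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 400)),
        min_size=1,
        max_size=60,
    )
)
@settings(deadline=None)
def test_merge_tile_conserve_bases_property(pairs):
    s = IntervalSet([GenomicInterval("chr1", a, a + w) for a, w in pairs])
    m = merge_intervals(s)
    assert m.total_bases() == len(brute_covered_positions(s))
    assert tile_windows(m, 100).total_bases() == m.total_bases()
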