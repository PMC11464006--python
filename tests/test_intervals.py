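"""Interval primitives: BED parsing, overlap/nearest arithmetic, liftover."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atacdeconv.intervals import (
    ChainAlignment,
    ChainBlock,
    GenomicRegion,
    PeakSet,
    liftover_regions,
    match_features,
    nearest_region,
    overlap_bp,
    parse_bed,
    pool_peaks,
    read_chain_file,
    write_bed,
)
from atacdeconv.intervals import BedParseError


def R(chrom, start, end, score=None):
    return GenomicRegion(chrom, start, end, score)


class TestGenomicRegion:
    def test_id_round_trips(self):
        r = R("chr1", 100, 200, 5.0)
        assert r.id == "chr1:100-200"
        back = GenomicRegion.from_id(r.id)
        assert (back.chrom, back.start, back.end) == ("chr1", 100, 200)

    @pytest.mark.parametrize(
        "chrom,start,end",
        [("chr1", 200, 100), ("chr1", -1, 100), ("", 0, 10), ("chr1", 50, 50)],
    )
    def test_invalid_coordinates_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicRegion(chrom, start, end)


class TestBedIO:
    def test_parse_bed3_and_bed5(self):
        ps = parse_bed(io.StringIO("chr1\t100\t200\nchr1\t300\t400\tpk\t37\n"))
        assert ps.ids == ("chr1:100-200", "chr1:300-400")
        assert ps[0].score is None
        assert ps[1].score == 37

    def test_comment_and_track_lines_skipped(self):
        ps = parse_bed(io.StringIO("# hello\ntrack name=x\nchr2\t5\t10\n"))
        assert len(ps) == 1

    @pytest.mark.parametrize(
        "text", ["chr1\t200\t100\n", "chr1\tx\t200\n", "chr1\t100\t200\tpk\tz\n"]
    )
    def test_malformed_lines_name_line_number(self, text):
        with pytest.raises(BedParseError, match="line 1"):
            parse_bed(io.StringIO(text))

    def test_write_parse_round_trip(self, rng):
        regions = [
            R(f"chr{c}", s, s + w, float(sc))
            for c, s, w, sc in zip(
                rng.integers(1, 4, 30), rng.integers(0, 10000, 30),
                rng.integers(1, 500, 30), rng.integers(0, 100, 30),
            )
        ]
        ps = pool_peaks([PeakSet(regions[i:i + 10]) for i in range(0, 30, 10)])
        buf = io.StringIO()
        write_bed(ps, buf)
        buf.seek(0)
        assert parse_bed(buf) == ps


class TestOverlapNearest:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (R("chr1", 100, 200), R("chr1", 150, 250), 50),
            (R("chr1", 100, 200), R("chr1", 200, 300), 0),  # abutting, half-open
            (R("chr1", 100, 200), R("chr2", 100, 200), 0),
            (R("chr1", 100, 200), R("chr1", 100, 200), 100),  # self = length
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        assert overlap_bp(a, b) == expected
        assert overlap_bp(b, a) == expected

    @pytest.mark.parametrize(
        "targets,expected",
        [
            ([("chr1", 150, 250)], (0, 0.0)),
            ([("chr1", 300, 400)], (0, 100.0)),
            ([("chr1", 0, 40), ("chr1", 250, 300)], (1, 50.0)),
        ],
    )
    def test_nearest_examples(self, targets, expected):
        ps = PeakSet([R(*t) for t in targets])
        assert nearest_region(R("chr1", 100, 200), ps) == expected

    def test_nearest_other_chrom_is_infinite(self):
        ps = PeakSet([R("chr2", 0, 10)])
        _, dist = nearest_region(R("chr1", 100, 200), ps)
        assert math.isinf(dist)

    def test_nearest_empty_targets_errors(self):
        with pytest.raises(ValueError):
            nearest_region(R("chr1", 0, 10), PeakSet([]))

    def test_nearest_ties_break_leftmost(self):
        ps = PeakSet([R("chr1", 0, 50), R("chr1", 300, 350)])
        idx, dist = nearest_region(R("chr1", 100, 250), ps)
        assert (idx, dist) == (0, 50.0)

    def test_brute_force_agreement(self, rng):
        """overlap/nearest match an exhaustive per-pair scan on random sets."""
        for _ in range(200):
            n = int(rng.integers(1, 15))
            targets = []
            seen = set()
            while len(targets) < n:
                c = f"chr{int(rng.integers(1, 4))}"
                s = int(rng.integers(0, 2000))
                e = s + int(rng.integers(1, 300))
                if (c, s, e) not in seen:
                    seen.add((c, s, e))
                    targets.append(R(c, s, e))
            ps = PeakSet(targets)
            qs = int(rng.integers(0, 2000))
            q = R(f"chr{int(rng.integers(1, 4))}", qs, qs + int(rng.integers(1, 300)))
            best_i, best_d = None, math.inf
            for i, t in enumerate(ps):
                if t.chrom != q.chrom:
                    continue
                d = 0.0 if overlap_bp(q, t) > 0 else float(
                    max(t.start, q.start) - min(t.end, q.end))
                if d < best_d:
                    best_i, best_d = i, d
            got_i, got_d = nearest_region(q, ps)
            assert got_d == best_d
            if best_i is not None:
                assert got_i == best_i


class TestMatchFeatures:
    def test_overlap_maps_non_overlap_none(self):
        bulk = PeakSet([R("chr1", 100, 200), R("chr1", 500, 600)])
        ref = PeakSet([R("chr1", 150, 250)])
        assert match_features(bulk, ref) == {0: 0, 1: None}

    def test_many_to_one(self):
        bulk = PeakSet([R("chr1", 100, 160), R("chr1", 170, 260)])
        ref = PeakSet([R("chr1", 150, 250)])
        assert match_features(bulk, ref) == {0: 0, 1: 0}

    def test_build_mismatch_mentions_liftover(self):
        bulk = PeakSet([R("chr1", 100, 200)], genome_build="hg19")
        ref = PeakSet([R("chr1", 100, 200)], genome_build="hg38")
        with pytest.raises(ValueError, match="lift"):
            match_features(bulk, ref)

    def test_permutation_invariant(self, rng):
        regions = [R("chr1", int(s), int(s) + 100) for s in rng.integers(0, 5000, 12) * 7]
        ref = PeakSet([R("chr1", 200, 900), R("chr1", 3000, 4000)])
        a = match_features(PeakSet(regions), ref)
        b = match_features(PeakSet(regions[::-1]), ref)
        assert a == b


class TestLiftover:
    def test_forward_offset(self):
        chain = ChainAlignment(
            score=100, source_chrom="chr1", source_size=20000, source_strand="+",
            source_start=0, source_end=10000, target_chrom="chr1",
            target_size=20000, target_strand="+", target_start=1000,
            target_end=11000, blocks=[ChainBlock(10000)],
        )
        lifted, dropped = liftover_regions(PeakSet([R("chr1", 100, 200)]), [chain])
        assert not dropped
        assert lifted.ids == ("chr1:1100-1200",)

    def test_gap_spanning_region_dropped(self):
        chain = ChainAlignment(
            score=100, source_chrom="chr1", source_size=20000, source_strand="+",
            source_start=0, source_end=1050, target_chrom="chr1",
            target_size=20000, target_strand="+", target_start=0, target_end=1000,
            blocks=[ChainBlock(500, source_gap=50), ChainBlock(500)],
        )
        lifted, dropped = liftover_regions(PeakSet([R("chr1", 480, 560)]), [chain])
        assert len(lifted) == 0
        assert dropped == [("chr1:480-560", "unmapped")]

    def test_reverse_strand_flip(self):
        """Hand-computed: one 500 bp block, target size 10000, reverse strand.

        Source position s maps to reverse-space position s, i.e. forward
        coordinate 10000 - 1 - s; the 100 bp region [100, 200) therefore maps
        to forward [9800, 9900) with length preserved.
        """
        chain = ChainAlignment(
            score=100, source_chrom="chr1", source_size=20000, source_strand="+",
            source_start=0, source_end=500, target_chrom="chrT",
            target_size=10000, target_strand="-", target_start=0, target_end=500,
            blocks=[ChainBlock(500)],
        )
        lifted, dropped = liftover_regions(PeakSet([R("chr1", 100, 200)]), [chain])
        assert not dropped
        (out,) = lifted
        assert (out.chrom, out.start, out.end) == ("chrT", 9800, 9900)
        # independent per-base oracle
        bases = sorted(10000 - 1 - s for s in range(100, 200))
        assert (out.start, out.end) == (bases[0], bases[-1] + 1)

    def test_no_chain_for_chrom(self):
        chain = ChainAlignment(
            score=100, source_chrom="chr2", source_size=20000, source_strand="+",
            source_start=0, source_end=100, target_chrom="chr2",
            target_size=20000, target_strand="+", target_start=0, target_end=100,
            blocks=[ChainBlock(100)],
        )
        _, dropped = liftover_regions(PeakSet([R("chr1", 0, 50)]), [chain])
        assert dropped == [("chr1:0-50", "no_chain")]

    def test_highest_scoring_chain_wins(self):
        mk = lambda score, off: ChainAlignment(
            score=score, source_chrom="chr1", source_size=20000, source_strand="+",
            source_start=0, source_end=1000, target_chrom="chr1",
            target_size=30000, target_strand="+", target_start=off,
            target_end=off + 1000, blocks=[ChainBlock(1000)],
        )
        lifted, _ = liftover_regions(PeakSet([R("chr1", 10, 20)]), [mk(5, 100), mk(50, 900)])
        assert lifted.ids == ("chr1:910-920",)

    def test_length_preserved_within_block(self, rng):
        chain = ChainAlignment(
            score=1, source_chrom="chr1", source_size=100000, source_strand="+",
            source_start=500, source_end=5500, target_chrom="chr1",
            target_size=100000, target_strand="+", target_start=7000,
            target_end=12000, blocks=[ChainBlock(5000)],
        )
        regions = [R("chr1", int(s), int(s) + int(w))
                   for s, w in zip(rng.integers(500, 5000, 20), rng.integers(1, 400, 20))]
        lifted, dropped = liftover_regions(pool_peaks([PeakSet(regions)]), [chain])
        assert not dropped
        lengths_in = sorted(r.length for r in set(regions))
        assert sorted(r.length for r in lifted) == lengths_in

    def test_chain_file_reader(self, tmp_path):
        text = (
            "chain 4900 chr1 20000 + 0 1050 chr1 20000 + 0 1000 1\n"
            "500 50 0\n"
            "500\n"
            "\n"
            "chain 100 chr2 5000 + 10 110 chrX 9000 - 20 120 2\n"
            "100\n"
        )
        path = tmp_path / "toy.chain"
        path.write_text(text)
        chains = read_chain_file(str(path))
        assert len(chains) == 2
        assert chains[0].blocks == [ChainBlock(500, 50, 0), ChainBlock(500)]
        assert chains[1].target_strand == "-"
        assert chains[1].source_chrom == "chr2"


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.integers(1, 300)),
        min_size=1, max_size=20, unique=True,
    )
)
def test_overlap_self_equals_length(coords):
    """overlap(a, a) == length(a) under half-open arithmetic."""
    for s, w in coords:
        r = R("chr1", s, s + w)
        assert overlap_bp(r, r) == w
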