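import random

import numpy as np
import pytest

from capscaffold.alignment_filters import AlignedRead
from capscaffold.io_formats import AnnotationIndex, Transcript
from capscaffold.tss_analysis import (
    closest_tss_distance,
    distance_cdf,
    find_novel_tss,
    marker_matrix,
    marker_overlap,
    merge_five_prime_ends,
)

from oracles import oracle_closest_tss, oracle_single_linkage


def _tx(chrom="chr1", strand="+", tss=1000, tes=2000, tid="T1", gid="G1",
        gtype="protein_coding"):
    return Transcript(chrom, strand, tss, tes, tid, gid, gid, gtype)


def _aln(read_id="r", chrom="chr1", strand="+", start=100, end=200, mapq=60):
    flags = 0 if strand == "+" else 16
    return AlignedRead(read_id, chrom, strand, start, end, f"{end - start}M",
                       mapq, flags)


def _aln_at_5p(pos, strand="+", chrom="chr1", read_id="r"):
    """Alignment whose 5' end sits exactly at ``pos``."""
    if strand == "+":
        return _aln(read_id, chrom, strand, pos, pos + 100)
    return _aln(read_id, chrom, strand, pos - 99, pos + 1)


class TestClosestTssDistance:
    def test_exact_hit_is_zero(self):
        ann = AnnotationIndex([_tx(tss=1000)])
        d = closest_tss_distance(_aln_at_5p(1000), ann)
        assert d.signed_distance == 0

    def test_upstream_on_plus_strand_is_negative(self):
        ann = AnnotationIndex([_tx(tss=1000)])
        d = closest_tss_distance(_aln_at_5p(960), ann)
        assert d.signed_distance == -40

    def test_upstream_sign_flips_on_minus_strand(self):
        # 40 nt genomically left of a minus-strand TSS = downstream = +40
        ann = AnnotationIndex([_tx(strand="-", tss=1000, tes=200)])
        d = closest_tss_distance(_aln_at_5p(960, strand="-"), ann)
        assert d.signed_distance == +40

    def test_unannotated_chromosome_flagged(self):
        ann = AnnotationIndex([_tx(chrom="chr2")])
        assert closest_tss_distance(_aln_at_5p(100), ann) is None

    def test_matches_brute_force_on_fuzzed_annotations(self):
        rng = random.Random(4)
        for _ in range(30):
            txs = [
                _tx(
                    chrom=rng.choice(["chr1", "chr2"]),
                    strand=rng.choice("+-"),
                    tss=rng.randint(0, 5000),
                    tes=rng.randint(0, 5000),
                    tid=f"T{k}",
                )
                for k in range(rng.randint(1, 100))
            ]
            ann = AnnotationIndex(txs)
            for _ in range(20):
                strand = rng.choice("+-")
                pos = rng.randint(100, 4900)
                read = _aln_at_5p(pos, strand=strand)
                got = closest_tss_distance(read, ann)
                want = oracle_closest_tss("chr1", strand, pos, txs)
                if want is None:
                    assert got is None
                else:
                    assert got.signed_distance == want[0]
                    assert got.closest_tss.transcript_id == want[1].transcript_id


class TestDistanceCdf:
    def test_direct_count(self):
        frac, table = distance_cdf([0, 10, -500], window=300)
        assert frac == pytest.approx(2 / 3)
        assert table["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_all_zero(self):
        frac, _ = distance_cdf([0, 0, 0], window=300)
        assert frac == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            distance_cdf([])


class TestFindNovelTss:
    def _setup(self, positions, strand="+", tss=10_000):
        ann = AnnotationIndex([_tx(tss=tss, tes=tss + 1000, strand=strand)])
        reads = [
            _aln_at_5p(p, strand=strand, read_id=f"r{i}")
            for i, p in enumerate(positions)
        ]
        return reads, ann

    def test_two_reads_within_linkage_form_cluster(self):
        reads, ann = self._setup([400, 450])  # 9600 and 9550 nt from TSS
        clusters = find_novel_tss(reads, ann)
        assert len(clusters) == 1 and clusters[0].size == 2
        assert clusters[0].representative_pos == 400

    def test_singleton_not_reported(self):
        reads, ann = self._setup([400])
        assert find_novel_tss(reads, ann) == []

    def test_gap_51_splits(self):
        reads, ann = self._setup([400, 451])
        assert find_novel_tss(reads, ann) == []

    def test_min_dist_boundary_inclusive(self):
        # ">= 300 bases away" retained; 299 still counts as annotated
        reads_at_300, ann = self._setup([10_000 - 300, 10_000 - 300])
        assert len(find_novel_tss(reads_at_300, ann)) == 1
        reads_at_299, ann = self._setup([10_000 - 299, 10_000 - 299])
        assert find_novel_tss(reads_at_299, ann) == []

    def test_order_independent(self):
        rng = random.Random(8)
        positions = [rng.randint(0, 3000) for _ in range(40)]
        reads, ann = self._setup(positions)
        clusters_a = find_novel_tss(reads, ann)
        rng.shuffle(reads)
        clusters_b = find_novel_tss(reads, ann)
        key = lambda c: (c.chrom, c.strand, c.representative_pos)
        assert sorted([sorted(c.member_read_ids) for c in clusters_a]) == sorted(
            [sorted(c.member_read_ids) for c in clusters_b]
        )
        assert sorted(map(key, clusters_a)) == sorted(map(key, clusters_b))

    def test_every_member_satisfies_distance_predicate(self):
        rng = random.Random(9)
        positions = [rng.randint(0, 20_000) for _ in range(200)]
        reads, ann = self._setup(positions)
        by_id = {r.read_id: r for r in reads}
        for cluster in find_novel_tss(reads, ann, min_dist=300):
            for rid in cluster.member_read_ids:
                d = closest_tss_distance(by_id[rid], ann)
                assert abs(d.signed_distance) >= 300

    def test_minus_strand_representative_is_five_prime_most(self):
        ann = AnnotationIndex([_tx(strand="-", tss=50_000, tes=40_000)])
        reads = [
            _aln_at_5p(p, strand="-", read_id=f"r{i}")
            for i, p in enumerate([1000, 1030])
        ]
        clusters = find_novel_tss(reads, ann)
        assert clusters[0].representative_pos == 1030  # 5'-most on minus strand


class TestMergeFivePrimeEnds:
    def test_chained_merge(self):
        assert merge_five_prime_ends([100, 120, 160], window=25) == [100, 160]

    def test_singleton_and_duplicates(self):
        assert merge_five_prime_ends([42]) == [42]
        assert merge_five_prime_ends([100, 100, 100]) == [100]

    def test_matches_single_linkage_oracle(self):
        rng = random.Random(12)
        for _ in range(50):
            positions = [rng.randint(0, 500) for _ in range(rng.randint(1, 40))]
            got = merge_five_prime_ends(positions, window=25)
            want = [g[0] for g in oracle_single_linkage(positions, 25)]
            # oracle groups keep duplicates; representatives are group minima
            assert got == sorted(set(want))


class TestMarkerOverlap:
    def test_end_inside_peak(self):
        frac, hits = marker_overlap([("chr1", 150)], [("chr1", 100, 200, None)])
        assert frac == 1.0 and hits == [True]

    def test_no_markers(self):
        frac, hits = marker_overlap([("chr1", 150)], [])
        assert frac == 0.0 and hits == [False]

    def test_half_open_boundary_at_zero_slop(self):
        markers = [("chr1", 100, 200, None)]
        assert marker_overlap([("chr1", 200)], markers)[1] == [False]
        assert marker_overlap([("chr1", 199)], markers)[1] == [True]
        assert marker_overlap([("chr1", 200)], markers, slop=1)[1] == [True]


class TestMarkerMatrix:
    def test_uniform_signal_gives_all_ones(self):
        points = [("chr1", 5000, "+")]
        signal = [("chr1", 0, 100_000, 1.0)]
        mat = marker_matrix(points, signal, flank=100)
        assert mat.shape == (1, 201) and np.all(mat == 1.0)

    def test_point_signal_lands_at_center_and_strand_flips(self):
        signal = [("chr1", 5000, 5001, 2.0)]
        mat = marker_matrix([("chr1", 4990, "+")], signal, flank=20)
        assert mat[0, 30] == 2.0 and mat.sum() == 2.0  # offset +10
        mat_minus = marker_matrix([("chr1", 4990, "-")], signal, flank=20)
        assert mat_minus[0, 10] == 2.0  # mirrored to offset -10

    def test_downsample_clamps_and_merges(self):
        points = [("chr1", p, "+") for p in (100, 120, 500)]
        mat = marker_matrix(points, [], flank=10, downsample_n=99, merge_window=50)
        assert mat.shape[0] == 2  # 100/120 merged, 500 separate; clamp, no error
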