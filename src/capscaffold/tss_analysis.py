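"""Distance-to-TSS statistics, novel-TSS clustering, 5'-end merging, and
orthogonal-marker overlap.

Sign convention for distances, per the annotated transcript's strand:
negative = upstream (5') of the annotated TSS, positive = downstream.
On ``+`` that is read_5p - tss; on ``-`` it is tss - read_5p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment_filters import AlignedRead
from .io_formats import AnnotationIndex, Transcript

__all__ = [
    "TssDistance",
    "TssCluster",
    "closest_tss_distance",
    "distance_cdf",
    "find_novel_tss",
    "merge_five_prime_ends",
    "marker_overlap",
    "marker_matrix",
]


@dataclass
class TssDistance:
    read_id: str
    signed_distance: int
    closest_tss: Transcript


@dataclass
class TssCluster:
    """A group of unannotated 5' ends supporting one candidate novel TSS."""

    chrom: str
    strand: str
    representative_pos: int  # 5'-most member position
    member_read_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_read_ids)


def _nearest(positions: np.ndarray, pos: int) -> int | None:
    """Index of the nearest value in a sorted array; ties prefer the
    earlier (left) element, matching first-in-sorted-order tie-breaks."""
    if positions.size == 0:
        return None
    i = int(np.searchsorted(positions, pos))
    if i == 0:
        idx = 0
    elif i == positions.size:
        idx = i - 1
    else:
        # left candidate wins distance ties (<=): first in sorted order
        idx = i - 1 if pos - positions[i - 1] <= positions[i] - pos else i
    # collapse runs of duplicate positions to their first occurrence
    return int(np.searchsorted(positions, positions[idx], side="left"))


def closest_tss_distance(
    aligned_read: AlignedRead, annotation: AnnotationIndex
) -> TssDistance | None:
    """Signed distance from the read's 5' end to the nearest same-strand
    annotated transcript TSS on its chromosome, or None when the
    chromosome/strand has no annotation (read flagged by the caller)."""
    positions, txs = annotation.tss_index(aligned_read.chrom, aligned_read.strand)
    idx = _nearest(positions, aligned_read.five_prime_pos)
    if idx is None:
        return None
    tx = txs[idx]
    p = aligned_read.five_prime_pos
    signed = p - tx.tss_pos if tx.strand == "+" else tx.tss_pos - p
    return TssDistance(aligned_read.read_id, int(signed), tx)


def distance_cdf(distances, window: int = 300) -> tuple[float, pd.DataFrame]:
    """Fraction of 5' ends with |distance| <= window, plus the full
    cumulative table (distance, count, cumulative fraction of total)."""
    d = np.asarray(list(distances), dtype=int)
    if d.size == 0:
        raise ValueError("empty distance list")
    frac = float(np.mean(np.abs(d) <= window))
    values, counts = np.unique(d, return_counts=True)
    table = pd.DataFrame(
        {
            "distance": values,
            "count": counts,
            "cumulative_fraction": np.cumsum(counts) / d.size,
        }
    )
    return frac, table


def _single_linkage(positions: np.ndarray, gap: int) -> list[np.ndarray]:
    """Split sorted positions where adjacent gap exceeds ``gap``."""
    if positions.size == 0:
        return []
    breaks = np.nonzero(np.diff(positions) > gap)[0] + 1
    return np.split(positions, breaks)


def find_novel_tss(
    aligned_reads: list[AlignedRead],
    annotation: AnnotationIndex,
    min_dist: int = 300,
    link_dist: int = 50,
    min_reads: int = 2,
) -> list[TssCluster]:
    """Cluster 5' ends far from every annotated TSS into candidate novel TSS.

    Reads whose |signed distance| to the nearest same-strand annotated
    TSS is >= min_dist are retained (reads on unannotated chromosomes
    are also far from every TSS and are retained); retained 5' ends are
    single-linkage clustered per (chrom, strand) with adjacent gap <=
    link_dist, and clusters with fewer than min_reads members are
    discarded.  The representative is the 5'-most member position.
    Clustering is order-independent: positions are sorted internally.
    """
    far: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for read in aligned_reads:
        dist = closest_tss_distance(read, annotation)
        if dist is not None and abs(dist.signed_distance) < min_dist:
            continue
        far.setdefault((read.chrom, read.strand), []).append(
            (read.five_prime_pos, read.read_id)
        )
    clusters: list[TssCluster] = []
    for (chrom, strand), members in sorted(far.items()):
        members.sort()
        positions = np.array([p for p, _ in members])
        start = 0
        for group in _single_linkage(positions, link_dist):
            chunk = members[start : start + group.size]
            start += group.size
            if group.size < min_reads:
                continue
            rep = int(group.min()) if strand == "+" else int(group.max())
            clusters.append(
                TssCluster(chrom, strand, rep, [rid for _, rid in chunk])
            )
    return clusters


def merge_five_prime_ends(
    positions, strand: str = "+", window: int = 25
) -> list[int]:
    """Merge 5' ends within ``window`` nt (single linkage) into unique ends.

    One representative per merged group, the 5'-most member (minimum
    position on ``+``, maximum on ``-``).
    """
    pos = np.sort(np.asarray(list(positions), dtype=int))
    reps = []
    for group in _single_linkage(pos, window):
        reps.append(int(group.min()) if strand == "+" else int(group.max()))
    return reps


def _build_trees(marker_intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, _strand in marker_intervals:
        if end <= start:
            continue
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def marker_overlap(
    unique_ends: list[tuple[str, int]],
    marker_intervals,
    slop: int = 0,
) -> tuple[float, list[bool]]:
    """Fraction of unique 5' ends falling within ``slop`` nt of any
    marker interval (half-open; an end 1 nt outside at slop=0 does not
    overlap).  Marker strand is ignored — chromatin marks are unstranded."""
    trees = _build_trees(marker_intervals)
    hits = []
    for chrom, pos in unique_ends:
        tree = trees.get(chrom)
        hits.append(bool(tree is not None and tree.overlap(pos - slop, pos + slop + 1)))
    fraction = float(np.mean(hits)) if hits else 0.0
    return fraction, hits


def marker_matrix(
    reference_points: list[tuple[str, int, str]],
    signal_intervals,
    flank: int = 1000,
    downsample_n: int | None = None,
    merge_window: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Signal matrix around reference points (deepTools-like layout).

    Reference points (chrom, pos, strand) are merged per (chrom, strand)
    within ``merge_window`` nt to avoid repeats, then down-sampled to
    ``downsample_n`` rows without replacement (seeded; clamped when
    fewer rows exist).  Each row holds the signal value at strand-
    oriented offsets -flank..+flank; signal comes from scored intervals
    (chrom, start, end, value), last interval wins on overlap.
    """
    merged: list[tuple[str, int, str]] = []
    by_key: dict[tuple[str, str], list[int]] = {}
    for chrom, pos, strand in reference_points:
        by_key.setdefault((chrom, strand), []).append(pos)
    for (chrom, strand), positions in sorted(by_key.items()):
        for rep in merge_five_prime_ends(positions, strand, merge_window):
            merged.append((chrom, rep, strand))
    rng = np.random.default_rng(seed)
    if downsample_n is not None and downsample_n < len(merged):
        idx = rng.choice(len(merged), size=downsample_n, replace=False)
        merged = [merged[i] for i in sorted(idx)]

    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for item in signal_intervals:
        chrom, start, end, value = item[0], item[1], item[2], item[3]
        by_chrom.setdefault(chrom, []).append((start, end, float(value)))

    width = 2 * flank + 1
    matrix = np.zeros((len(merged), width))
    for row, (chrom, pos, strand) in enumerate(merged):
        lo, hi = pos - flank, pos + flank + 1
        for start, end, value in by_chrom.get(chrom, []):
            a, b = max(start, lo), min(end, hi)
            if a < b:
                matrix[row, a - lo : b - lo] = value
        if strand == "-":
            matrix[row] = matrix[row, ::-1]
    return matrix
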