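"""The full cascade producing high-confidence full-length RNA scaffolds.

A full-length poly(A) RNA scaffold is a single read that passes, in
order: the mean-quality gate (Q>=7), cap-adapter detection, the
true-positive cross-check, the 5' clip filter, the poly(A) tail filter
(positive nanopolish-style tail call), and the poly(A) site filter
(aligned 3' end within -60..+10 nt of an annotated cleavage site, the
window recommended by the PolyASite atlas — it removes RNAs that were
poly(A)-tailed mid-gene during degradation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_filters import AlignedRead, DEFAULT_CLIP_REMOVE
from .io_formats import AnnotationIndex, PolyASiteIndex, PolyATailTable
from .tss_analysis import _nearest, closest_tss_distance

__all__ = [
    "ScaffoldCall",
    "STAGES",
    "polya_site_distance",
    "polya_site_filter",
    "call_scaffolds",
    "funnel_counts",
    "full_length_untreated",
    "classify_gene_type",
    "gene_counts_cpm",
    "correlate_cpm",
    "mapq_summary",
]

#: cascade stage names, in the order they are applied.
STAGES = (
    "quality_pass",
    "cap_adapted",
    "true_positive_confirmed",
    "clip_pass",
    "polya_tail_pass",
    "polya_site_pass",
)


@dataclass
class ScaffoldCall:
    """Per-read cascade verdict; a read failing stage k has all later
    stage booleans False."""

    read_id: str
    stages: dict[str, bool]
    gene_id: str | None = None
    gene_type: str | None = None
    mapq: int | None = None
    polya_site_distance: int | None = None
    is_novel_tss: bool = False

    @property
    def is_full_length(self) -> bool:
        return all(self.stages[s] for s in STAGES)


def polya_site_distance(
    aligned_read: AlignedRead, polya_index: PolyASiteIndex
) -> int | None:
    """Signed distance from the read's 3' end to the nearest same-strand
    annotated poly(A) site: negative = upstream of the site (internal to
    the gene), positive = downstream.  None when no site exists on the
    chromosome/strand (the read then fails the site filter)."""
    positions = polya_index.positions(aligned_read.chrom, aligned_read.strand)
    idx = _nearest(positions, aligned_read.three_prime_pos)
    if idx is None:
        return None
    site = int(positions[idx])
    e = aligned_read.three_prime_pos
    return e - site if aligned_read.strand == "+" else site - e


def polya_site_filter(
    distance: int | None, window: tuple[int, int] = (-60, 10)
) -> bool:
    """Pass iff the 3'-end distance lies within the inclusive window."""
    if distance is None:
        return False
    lo, hi = window
    return lo <= distance <= hi


def call_scaffolds(
    reads,
    adapter_calls,
    confirmed_ids: set[str],
    alignments: list[AlignedRead],
    polya_table: PolyATailTable,
    polya_index: PolyASiteIndex,
    annotation: AnnotationIndex,
    q_min: float = 7.0,
    clip_remove: int = DEFAULT_CLIP_REMOVE,
    polya_window: tuple[int, int] = (-60, 10),
    novel_tss_ids: set[str] | None = None,
) -> list[ScaffoldCall]:
    """Apply the cascade to every read and return per-read verdicts.

    ``alignments`` are the primary alignments of the *trimmed* reads;
    ``confirmed_ids`` is the output of the true-positive filter.  A read
    missing from any keyed input fails the corresponding stage; it never
    aborts the run.  ``novel_tss_ids`` (cluster membership from
    find_novel_tss) marks the novel-TSS subset of full-length scaffolds.
    """
    mean_q = {r.read_id: r.mean_q for r in reads}
    detected = {c.read_id: c.detected for c in adapter_calls}
    aln_by_id = {a.read_id: a for a in alignments}
    novel_tss_ids = novel_tss_ids or set()

    calls: list[ScaffoldCall] = []
    for read_id in mean_q:
        stages = dict.fromkeys(STAGES, False)
        call = ScaffoldCall(read_id, stages)
        aln = aln_by_id.get(read_id)
        if aln is not None:
            call.mapq = aln.mapq
            tss = closest_tss_distance(aln, annotation)
            if tss is not None:
                call.gene_id = tss.closest_tss.gene_id
                call.gene_type = tss.closest_tss.gene_type
        stages["quality_pass"] = mean_q[read_id] >= q_min
        if stages["quality_pass"]:
            stages["cap_adapted"] = detected.get(read_id, False)
        if stages["cap_adapted"]:
            stages["true_positive_confirmed"] = read_id in confirmed_ids
        if stages["true_positive_confirmed"]:
            stages["clip_pass"] = aln is not None and aln.five_prime_clip < clip_remove
        if stages["clip_pass"]:
            stages["polya_tail_pass"] = polya_table.tail_pass(read_id)
        if stages["polya_tail_pass"]:
            call.polya_site_distance = polya_site_distance(aln, polya_index)
            stages["polya_site_pass"] = polya_site_filter(
                call.polya_site_distance, polya_window
            )
        call.is_novel_tss = call.is_full_length and read_id in novel_tss_ids
        calls.append(call)
    return calls


def funnel_counts(calls: list[ScaffoldCall]) -> pd.DataFrame:
    """Stage-by-stage survivor counts with percentages relative to the
    treated (input) read set and to the previous stage."""
    rows = []
    total = len(calls)
    prev = total
    rows.append({"stage": "treated", "count": total, "pct_of_treated": 100.0, "pct_of_previous": 100.0})
    for stage in STAGES:
        n = sum(1 for c in calls if c.stages[stage])
        rows.append(
            {
                "stage": stage,
                "count": n,
                "pct_of_treated": 100.0 * n / total if total else 0.0,
                "pct_of_previous": 100.0 * n / prev if prev else 0.0,
            }
        )
        prev = n
    return pd.DataFrame(rows)


def full_length_untreated(
    aligned_read: AlignedRead,
    annotation: AnnotationIndex,
    w5: int = 25,
    w3: int = 50,
) -> bool:
    """Full-length by the annotation-window definition used for
    untreated reads: some same-strand transcript has its annotated 5'
    end within w5 nt of the read 5' end and its annotated 3' end within
    w3 nt of the read 3' end (both windows inclusive)."""
    positions, txs = annotation.tss_index(aligned_read.chrom, aligned_read.strand)
    p5, p3 = aligned_read.five_prime_pos, aligned_read.three_prime_pos
    lo = int(np.searchsorted(positions, p5 - w5, side="left"))
    hi = int(np.searchsorted(positions, p5 + w5, side="right"))
    return any(abs(txs[i].tes_pos - p3) <= w3 for i in range(lo, hi))


def classify_gene_type(
    aligned_reads: list[AlignedRead], annotation: AnnotationIndex
) -> pd.Series:
    """Fraction of reads per gene_type of the closest same-strand
    annotated transcript, normalized to 1 over assigned reads."""
    counts: dict[str, int] = {}
    for read in aligned_reads:
        dist = closest_tss_distance(read, annotation)
        if dist is None:
            continue
        gt = dist.closest_tss.gene_type
        counts[gt] = counts.get(gt, 0) + 1
    series = pd.Series(counts, dtype=float).sort_index()
    return series / series.sum() if len(series) else series


def gene_counts_cpm(assignments: dict[str, int]) -> pd.Series:
    """Counts-per-million from per-gene integer counts."""
    series = pd.Series(assignments, dtype=float).sort_index()
    total = series.sum()
    if total == 0:
        return series
    return series * 1e6 / total


def correlate_cpm(table_a: pd.Series, table_b: pd.Series) -> float:
    """Spearman rank correlation over the union of genes (absent = 0)."""
    genes = table_a.index.union(table_b.index)
    a = table_a.reindex(genes, fill_value=0.0)
    b = table_b.reindex(genes, fill_value=0.0)
    rho, _ = stats.spearmanr(a, b)
    return float(rho)


@dataclass
class MapqSummary:
    histogram: np.ndarray  # counts for MAPQ 0..60
    q0_fraction: float
    q60_fraction: float
    n: int = field(default=0)


def mapq_summary(mapqs) -> MapqSummary:
    """Histogram over MAPQ 0-60 with headline Q0/Q60 fractions.

    MAPQ 0 marks ambiguous placement (multiple equally good positions),
    60 essentially unique placement.
    """
    q = np.asarray(list(mapqs), dtype=int)
    hist = np.bincount(q, minlength=61)[:61] if q.size else np.zeros(61, dtype=int)
    n = q.size
    return MapqSummary(
        histogram=hist,
        q0_fraction=float(hist[0] / n) if n else 0.0,
        q60_fraction=float(hist[60] / n) if n else 0.0,
        n=n,
    )
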