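"""Strand-aware filtering of splice-aware alignments.

Consumes SAM/BAM produced externally (splice-aware alignment is
off-the-shelf, not re-implemented here); applies primary-only
selection, the 5' clip threshold, and the dual-alignment true-positive
cross-check that rejects adapter calls where the "adapter" sequence is
actually genomic.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

__all__ = [
    "AlignedRead",
    "read_sam",
    "select_primary",
    "five_prime_clip",
    "clip_filter",
    "true_positive_filter",
    "DEFAULT_CLIP_REMOVE",
]

#: alignments with >= this many 5'-clipped bases are removed (keep <= 14).
DEFAULT_CLIP_REMOVE = 15

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlignedRead:
    """One spliced alignment with strand-aware derived ends.

    five_prime_pos/three_prime_pos are genomic coordinates of the read's
    biological 5'/3' ends: on ``+`` the 5' end is ref_start and the 3'
    end ref_end-1; on ``-`` they mirror.  five_prime_clip sums soft and
    hard clip lengths at the 5' end of the *read* (leading CIGAR ops on
    ``+``, trailing on ``-``).
    """

    read_id: str
    chrom: str
    strand: str
    ref_start: int  # 0-based half-open
    ref_end: int
    cigar: str
    mapq: int
    flags: int

    @property
    def five_prime_pos(self) -> int:
        return self.ref_start if self.strand == "+" else self.ref_end - 1

    @property
    def three_prime_pos(self) -> int:
        return self.ref_end - 1 if self.strand == "+" else self.ref_start

    @property
    def five_prime_clip(self) -> int:
        return five_prime_clip(self.cigar, self.strand)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def five_prime_clip(cigar: str, strand: str) -> int:
    """Sum of S and H clip lengths at the read's 5' end.

    The 5' end of a direct-RNA read is the leading end of the CIGAR on
    ``+`` and the trailing end on ``-`` (SAM stores the reverse
    complement for minus-strand alignments).
    """
    ops = parse_cigar(cigar)
    if strand == "-":
        ops = ops[::-1]
    total = 0
    for length, op in ops:
        if op in "SH":
            total += length
        else:
            break
    return total


def read_sam(path) -> Iterator[AlignedRead]:
    """Stream mapped records from SAM/BAM as AlignedRead (all flags kept)."""
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                cigar=rec.cigarstring,
                mapq=rec.mapping_quality,
                flags=rec.flag,
            )


def select_primary(alignments: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Keep only primary alignments: drop secondary (0x100) and
    supplementary (0x800) records; at most one record per read id
    (duplicate primaries keep the first, with a warning)."""
    seen: set[str] = set()
    kept: list[AlignedRead] = []
    duplicates = 0
    for aln in alignments:
        if aln.flags & 0x4 or aln.flags & 0x100 or aln.flags & 0x800:
            continue
        if aln.read_id in seen:
            duplicates += 1
            continue
        seen.add(aln.read_id)
        kept.append(aln)
    if duplicates:
        warnings.warn(f"dropped {duplicates} duplicate primary record(s), kept first")
    return kept


def clip_filter(
    aligned_reads: Iterable[AlignedRead], clip_remove: int = DEFAULT_CLIP_REMOVE
) -> list[AlignedRead]:
    """Remove alignments with clip_remove or more 5'-clipped bases.

    The default (15) keeps reads with at most 14 clipped bases; this is
    the released-pipeline reading of the threshold, and ``clip_remove=16``
    reproduces the alternative keep-up-to-15 reading.
    """
    return [a for a in aligned_reads if a.five_prime_clip < clip_remove]


def true_positive_filter(
    detected_ids: Iterable[str],
    untrimmed_alignments: Iterable[AlignedRead],
    trimmed_alignments: Iterable[AlignedRead],
    clip_remove: int = DEFAULT_CLIP_REMOVE,
) -> tuple[set[str], dict[str, int]]:
    """Cross-check adapter calls against untrimmed vs trimmed alignments.

    A genuine cap-adapter is not genomic sequence, so the *untrimmed*
    read must carry it as a large 5' soft/hard clip (>= clip_remove).
    A detected read whose untrimmed alignment has a small 5' clip had
    its "adapter" aligned to the genome — a genomic decoy — and is
    removed from the cap-adapted set.  Confirmed reads must additionally
    pass the clip filter on their trimmed alignment.

    Returns (confirmed read ids, drop-reason counts).
    """
    untrimmed = {a.read_id: a for a in untrimmed_alignments}
    trimmed = {a.read_id: a for a in trimmed_alignments}
    confirmed: set[str] = set()
    dropped = {"missing_alignment": 0, "genomic_adapter": 0, "trimmed_clip": 0}
    for read_id in detected_ids:
        u, t = untrimmed.get(read_id), trimmed.get(read_id)
        if u is None or t is None:
            dropped["missing_alignment"] += 1
            continue
        if u.five_prime_clip < clip_remove:
            dropped["genomic_adapter"] += 1
            continue
        if t.five_prime_clip >= clip_remove:
            dropped["trimmed_clip"] += 1
            continue
        confirmed.add(read_id)
    return confirmed, dropped
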