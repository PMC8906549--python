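"""5' RACE validation of candidate TSS.

RACE libraries carry a 5-nt index ligated to the R1 5' end that records
whether the RNA came from the decapped (RppH-treated) or mock-treated
sample.  Only originally capped 5' ends yield treated-sample products,
so a candidate TSS is validated when the treated fraction of RACE reads
near it exceeds 0.5 with at least one treated read.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DEFAULT_INDEX_MAP",
    "RaceCandidate",
    "demux_by_index",
    "validate_tss",
]

#: 5-nt ligated indexes: GATTA marks the RppH-treated (decapped) sample,
#: ATCAG the mock-treated control.
DEFAULT_INDEX_MAP = {"GATTA": "treated", "ATCAG": "untreated"}


@dataclass
class RaceCandidate:
    """One candidate TSS with its RACE read support and verdict."""

    candidate_id: str
    chrom: str
    strand: str
    tss_pos: int
    treated_count: int = 0
    untreated_count: int = 0

    @property
    def ratio(self) -> float | None:
        total = self.treated_count + self.untreated_count
        return self.treated_count / total if total else None

    @property
    def validated(self) -> bool:
        # strictly > 0.5, and at least one treated-sample read
        return (
            self.treated_count >= 1
            and self.ratio is not None
            and self.ratio > 0.5
        )


def demux_by_index(
    read_pairs,
    index_map: dict[str, str] | None = None,
) -> list[tuple[str, object, object]]:
    """Assign read pairs to samples by the anchored 5-nt index on R1.

    A pair is assigned iff R1 begins with the full index, matched
    exactly (the stated demultiplexer's 10% error tolerance on a 5-mer
    allows zero errors anyway); unassigned pairs are discarded.
    Returns (label, r1, r2) tuples.
    """
    index_map = DEFAULT_INDEX_MAP if index_map is None else index_map
    labeled = []
    for r1, r2 in read_pairs:
        matches = [
            label for index, label in index_map.items()
            if r1.sequence.upper().startswith(index.upper())
        ]
        if len(matches) > 1:
            raise ValueError(
                f"read {r1.read_id} matches multiple indexes; "
                "index set is not prefix-free"
            )
        if matches:
            labeled.append((matches[0], r1, r2))
    return labeled


def validate_tss(
    candidate: RaceCandidate,
    labeled_alignments,
    window: int = 100,
    ignore_strand: bool = False,
) -> RaceCandidate:
    """Count labeled R1 5' ends within the (inclusive, two-sided)
    window of the candidate TSS and derive the validation verdict.

    ``labeled_alignments`` yields (label, AlignedRead) for R1 only (R2
    is discarded upstream).  Reads on a different strand are excluded
    unless ignore_strand is set.
    """
    treated = untreated = 0
    for label, aln in labeled_alignments:
        if aln.chrom != candidate.chrom:
            continue
        if not ignore_strand and aln.strand != candidate.strand:
            continue
        if abs(aln.five_prime_pos - candidate.tss_pos) > window:
            continue
        if label == "treated":
            treated += 1
        elif label == "untreated":
            untreated += 1
    candidate.treated_count = treated
    candidate.untreated_count = untreated
    return candidate
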