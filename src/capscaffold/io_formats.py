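"""Readers/writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open.  GTF input (1-based,
closed) is shifted on read; BED input is taken as-is; every emitted BED
is 0-based half-open.  A single convention prevents off-by-one drift
across the downstream filters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "Transcript",
    "AnnotationIndex",
    "PolyASiteIndex",
    "PolyATailTable",
    "read_fastq",
    "write_fastq",
    "u_to_t",
    "mean_read_quality",
    "load_gtf_annotation",
    "load_bed_sites",
    "load_bed_intervals",
    "load_polya_table",
]

_U_TO_T = str.maketrans("Uu", "Tt")


@dataclass
class Read:
    """One basecalled read: sequence (ACGTU/N alphabet) plus per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    @property
    def mean_q(self) -> float:
        return mean_read_quality(self.qualities)


def u_to_t(sequence: str) -> str:
    """Replace U/u by T/t; everything else (case, N, unknowns) passes through."""
    return sequence.translate(_U_TO_T)


def mean_read_quality(qualities: Iterable[int], method: str = "error_prob") -> float:
    """Mean read quality in Phred units.

    ``error_prob`` (default) averages per-base error probabilities and
    converts back, -10*log10(mean(10**(-q/10))) — the ONT/NanoFilt
    convention, which weights low-quality bases more heavily than the
    plain arithmetic mean (available as ``method="arithmetic"``).
    """
    q = np.asarray(list(qualities), dtype=float)
    if q.size == 0:
        raise ValueError("cannot compute mean quality of an empty quality vector")
    if method == "error_prob":
        return float(-10.0 * math.log10(np.mean(10.0 ** (-q / 10.0))))
    if method == "arithmetic":
        return float(np.mean(q))
    raise ValueError(f"unknown mean-quality method {method!r}")


def read_fastq(path) -> Iterator[Read]:
    """Stream Phred+33 FASTQ records in file order.

    The sequence alphabet is preserved verbatim (U stays U); conversion
    is an explicit, separate step.
    """
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                read_id = title.split(None, 1)[0]
                yield Read(read_id, seq, [ord(c) - 33 for c in qual])
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], handle_or_path) -> None:
    """Write 4-line Phred+33 FASTQ; round-trips byte-identically with read_fastq."""
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    handle: TextIO = open(handle_or_path, "w") if own else handle_or_path
    try:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
    finally:
        if own:
            handle.close()


@dataclass(frozen=True)
class Transcript:
    chrom: str
    strand: str
    tss_pos: int  # 0-based position of the 5'-most transcribed base
    tes_pos: int  # 0-based position of the 3'-most transcribed base
    transcript_id: str
    gene_id: str
    gene_name: str
    gene_type: str


class AnnotationIndex:
    """Strand-indexed transcript TSS/TES records with gene_type.

    One entry per transcript (GENCODE ``annotated TSS`` is per transcript,
    not per collapsed gene).  Lookups by (chrom, strand) return positions
    sorted ascending, aligned with a transcript list in the same order.
    """

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: list[Transcript] = list(transcripts)
        self._tss: dict[tuple[str, str], tuple[np.ndarray, list[Transcript]]] = {}
        self._tes: dict[tuple[str, str], tuple[np.ndarray, list[Transcript]]] = {}
        by_key: dict[tuple[str, str], list[Transcript]] = {}
        for t in self.transcripts:
            by_key.setdefault((t.chrom, t.strand), []).append(t)
        for key, txs in by_key.items():
            by_tss = sorted(txs, key=lambda t: (t.tss_pos, t.transcript_id))
            self._tss[key] = (np.array([t.tss_pos for t in by_tss]), by_tss)
            by_tes = sorted(txs, key=lambda t: (t.tes_pos, t.transcript_id))
            self._tes[key] = (np.array([t.tes_pos for t in by_tes]), by_tes)

    def tss_index(self, chrom: str, strand: str):
        return self._tss.get((chrom, strand), (np.empty(0, dtype=int), []))

    def tes_index(self, chrom: str, strand: str):
        return self._tes.get((chrom, strand), (np.empty(0, dtype=int), []))

    def __len__(self) -> int:
        return len(self.transcripts)


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def load_gtf_annotation(path) -> AnnotationIndex:
    """Load transcript records from a GENCODE-dialect GTF.

    TSS/TES are derived strand-aware from the transcript span: on ``+``
    the TSS is the GTF start (shifted to 0-based) and the TES the GTF
    end; on ``-`` they swap.  Transcripts without a strand are skipped
    (counted in a warning).
    """
    transcripts: list[Transcript] = []
    skipped = 0
    with open(path) as handle:
        for line in handle:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "transcript":
                continue
            chrom, _, _, start, end, _, strand, _, attr_field = fields[:9]
            if strand not in ("+", "-"):
                skipped += 1
                continue
            attrs = _parse_gtf_attributes(attr_field)
            start0 = int(start) - 1  # GTF is 1-based closed
            end0 = int(end) - 1
            tss, tes = (start0, end0) if strand == "+" else (end0, start0)
            transcripts.append(
                Transcript(
                    chrom=chrom,
                    strand=strand,
                    tss_pos=tss,
                    tes_pos=tes,
                    transcript_id=attrs.get("transcript_id", ""),
                    gene_id=attrs.get("gene_id", ""),
                    gene_name=attrs.get("gene_name", attrs.get("gene_id", "")),
                    gene_type=attrs.get("gene_type", attrs.get("gene_biotype", "")),
                )
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} transcript(s) lacking strand")
    return AnnotationIndex(transcripts)


class PolyASiteIndex:
    """Per-strand sorted index of single-base cleavage sites (0-based)."""

    def __init__(self, sites: Iterable[tuple[str, str, int]]):
        self.sites = sorted(set(sites))
        self._by_key: dict[tuple[str, str], np.ndarray] = {}
        grouped: dict[tuple[str, str], list[int]] = {}
        for chrom, strand, pos in self.sites:
            grouped.setdefault((chrom, strand), []).append(pos)
        for key, positions in grouped.items():
            self._by_key[key] = np.array(sorted(positions))

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        return self._by_key.get((chrom, strand), np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.sites)


def load_bed_sites(path) -> PolyASiteIndex:
    """Load BED3/BED6 point features as single-base sites.

    An interval [start, end) is collapsed to its start coordinate (the
    representative base for one-base sites, the convention used
    throughout).  Records without a strand column are mirrored to both
    strands — marker files such as DNase peaks are unstranded.
    """
    sites: list[tuple[str, str, int]] = []
    for chrom, start, _end, strand in _iter_bed(path):
        if strand is None:
            sites.append((chrom, "+", start))
            sites.append((chrom, "-", start))
        else:
            sites.append((chrom, strand, start))
    return PolyASiteIndex(sites)


def load_bed_intervals(path) -> list[tuple[str, int, int, str | None]]:
    """Load BED intervals as (chrom, start, end, strand-or-None), 0-based half-open."""
    return list(_iter_bed(path))


def _iter_bed(path):
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                start, end = int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            yield fields[0], start, end, strand


@dataclass
class PolyATailTable:
    """Per-read poly(A) tail calls (nanopolish-polya style TSV).

    The closed-world rule applies: a read absent from the table has no
    tail evidence and fails the tail filter.
    """

    entries: dict[str, tuple[float, str]] = field(default_factory=dict)
    pass_label: str = "PASS"
    duplicate_count: int = 0

    def tail_pass(self, read_id: str) -> bool:
        entry = self.entries.get(read_id)
        return entry is not None and entry[1] == self.pass_label

    def tail_length(self, read_id: str) -> float | None:
        entry = self.entries.get(read_id)
        return None if entry is None else entry[0]

    def __len__(self) -> int:
        return len(self.entries)


def load_polya_table(path, pass_label: str = "PASS") -> PolyATailTable:
    """Load a TSV with columns readname, polya_length, qc_tag.

    Duplicate read ids keep the first occurrence and are counted.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("readname", "polya_length", "qc_tag"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    table = PolyATailTable(pass_label=pass_label)
    for readname, length, tag in zip(df["readname"], df["polya_length"], df["qc_tag"]):
        rid = str(readname)
        if rid in table.entries:
            table.duplicate_count += 1
            continue
        table.entries[rid] = (float(length), str(tag))
    if table.duplicate_count:
        warnings.warn(f"{path}: {table.duplicate_count} duplicate read id(s), kept first")
    return table
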