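"""Seeded generator of toy references and cap-adapted read sets with
planted truth for every filter stage.

The generator emulates the anatomy of recappable direct-RNA nanopore
reads — cap-adapter, spliced transcript body, poly(A) tail — plus the
failure modes the cascade is built to reject: 5'-truncated reads,
uncapped full-length reads, genomic adapter decoys (the adapter-like
sequence is part of the genome, so the untrimmed alignment has no 5'
clip), and degradation-tailed reads whose poly(A) tail was added
mid-gene.  Alignments are emitted as truth-based SAM directly, so the
suite never invokes an external aligner; the error model is
substitution-only (nanopore-like median identity 87% at the default
rate 0.13), which keeps the truth CIGARs valid.

Same seed, same config => byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adapter_detection import AdapterConfig, CAP_ADAPTER_DNA, adapter_identity
from .io_formats import Read, write_fastq

__all__ = ["SimConfig", "Gene", "Reference", "SimResult", "make_reference", "simulate_reads", "write_outputs"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one simulated run.

    Class fractions echo a recappable direct-RNA run: reads carrying a
    detectable adapter-like 5' end (genuine caps, degradation-tailed
    caps, genomic decoys) total 14.3% of treated reads, matching the
    observed cap-adaptation rate; most reads are 5'-truncated by strand
    breaks; frac_uncapped is the remainder.  tail_call_fail_rate is the
    fraction of reads whose signal-domain tail call fails (24.3% of
    alignment-filtered reads in the reference run), and genuine caps
    outnumber degradation-tailed caps 93.9:6.1, the observed site-filter
    survival.  Per-gene expression is log-normal (expression_sigma),
    emulating the skewed transcript-per-gene distribution real
    libraries show; uniform expression would make rank-correlation
    statistics degenerate.
    """

    seed: int = 0
    n_chroms: int = 2
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (100, 400)
    intron_length: tuple[int, int] = (80, 300)
    intergenic_length: tuple[int, int] = (300, 800)
    n_reads: int = 1000
    frac_capped: float = 0.100
    frac_truncated: float = 0.650
    frac_decoy: float = 0.036
    frac_degradation_tailed: float = 0.007
    substitution_rate: float = 0.13
    polya_length: tuple[int, int] = (20, 80)
    adapter_seq: str = CAP_ADAPTER_DNA
    identity_threshold: float = 74.0
    tail_call_fail_rate: float = 0.243
    frac_low_quality: float = 0.0
    frac_mapq0: float = 0.068
    frac_mapq_mid: float = 0.209  # leaves 72.3% at Q60
    expression_sigma: float = 1.0
    gene_types: tuple[tuple[str, float], ...] = (
        ("protein_coding", 0.8),
        ("lincRNA", 0.15),
        ("Mt_rRNA", 0.05),
    )
    # planted novel-TSS read groups (in addition to n_reads)
    n_novel_clusters: int = 0
    novel_cluster_size: tuple[int, int] = (2, 10)
    n_novel_singletons: int = 0
    novel_min_dist: int = 400
    degradation_min_internal: int = 100  # sense nt between 3' end and TES

    def __post_init__(self) -> None:
        total = (
            self.frac_capped
            + self.frac_truncated
            + self.frac_decoy
            + self.frac_degradation_tailed
        )
        if total > 1.0 + 1e-9:
            raise ValueError("class fractions sum above 1")

    @property
    def frac_uncapped(self) -> float:
        return 1.0 - (
            self.frac_capped
            + self.frac_truncated
            + self.frac_decoy
            + self.frac_degradation_tailed
        )


@dataclass
class Gene:
    gene_id: str
    transcript_id: str
    gene_name: str
    gene_type: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted
    is_decoy: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def tss_pos(self) -> int:
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def tes_pos(self) -> int:
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]


@dataclass
class Reference:
    chrom_seqs: dict[str, str]
    genes: list[Gene]

    def transcript_seq(self, gene: Gene) -> str:
        """Spliced transcript in sense orientation (5'->3')."""
        parts = [self.chrom_seqs[gene.chrom][s:e] for s, e in gene.exons]
        if gene.strand == "+":
            return "".join(parts)
        return "".join(_revcomp(p) for p in reversed(parts))


def sense_to_genomic_intervals(
    gene: Gene, s_off: int, e_off: int
) -> list[tuple[int, int]]:
    """Genomic pieces (sorted, half-open) covered by transcript sense
    offsets [s_off, e_off)."""
    pieces: list[tuple[int, int]] = []
    walked = 0
    exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
    for gs, ge in exons:
        length = ge - gs
        lo, hi = max(s_off, walked), min(e_off, walked + length)
        if lo < hi:
            if gene.strand == "+":
                pieces.append((gs + (lo - walked), gs + (hi - walked)))
            else:
                pieces.append((ge - (hi - walked), ge - (lo - walked)))
        walked += length
    pieces.sort()
    return pieces


def sense_to_genomic_pos(gene: Gene, off: int) -> int:
    """Genomic coordinate of one transcript sense base."""
    pieces = sense_to_genomic_intervals(gene, off, off + 1)
    return pieces[0][0]


def make_reference(config: SimConfig) -> Reference:
    """Toy genome + annotation: multi-exon genes on both strands, laid
    left to right with intergenic spacers; a tenth of the genes carry
    the cap-adapter sequence as the first 45 sense bases of their
    transcript (genomic decoy source genes)."""
    rng = np.random.default_rng(config.seed)
    chrom_parts: dict[str, list[str]] = {
        f"chr{i + 1}": [] for i in range(config.n_chroms)
    }
    chrom_len = {c: 0 for c in chrom_parts}
    genes: list[Gene] = []
    type_names = [t for t, _ in config.gene_types]
    type_probs = np.array([p for _, p in config.gene_types])
    type_probs = type_probs / type_probs.sum()
    n_decoy_genes = max(1, config.n_genes // 10)
    bases = np.array(list("ACGT"))

    def random_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    for gi in range(config.n_genes):
        chrom = f"chr{(gi % config.n_chroms) + 1}"
        spacer = int(rng.integers(*config.intergenic_length, endpoint=True))
        chrom_parts[chrom].append(random_seq(spacer))
        chrom_len[chrom] += spacer
        n_exons = int(rng.integers(*config.exons_per_gene, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = chrom_len[chrom]
        for ei in range(n_exons):
            if ei > 0:
                intron = int(rng.integers(*config.intron_length, endpoint=True))
                chrom_parts[chrom].append(random_seq(intron))
                pos += intron
            exon_len = int(rng.integers(*config.exon_length, endpoint=True))
            chrom_parts[chrom].append(random_seq(exon_len))
            exons.append((pos, pos + exon_len))
            pos += exon_len
        chrom_len[chrom] = pos
        genes.append(
            Gene(
                gene_id=f"GENE{gi:04d}",
                transcript_id=f"TX{gi:04d}",
                gene_name=f"SIMG{gi:04d}",
                gene_type=str(rng.choice(type_names, p=type_probs)),
                chrom=chrom,
                strand=strand,
                exons=exons,
                is_decoy=gi < n_decoy_genes,
            )
        )
    chrom_seqs = {c: "".join(parts) for c, parts in chrom_parts.items()}

    # plant the adapter into decoy genes' genomes: the first 45 sense
    # bases of the transcript become the adapter sequence, so reads from
    # these genes look cap-adapted while the "adapter" aligns perfectly
    adapter = config.adapter_seq
    for gene in genes:
        if not gene.is_decoy:
            continue
        pieces = sense_to_genomic_intervals(gene, 0, len(adapter))
        if gene.strand == "-":
            pieces = pieces[::-1]  # sense order walks right-to-left
        walked = 0
        for gs, ge in pieces:
            take = adapter[walked : walked + (ge - gs)]
            walked += ge - gs
            if gene.strand == "-":
                take = _revcomp(take)
            seq = chrom_seqs[gene.chrom]
            chrom_seqs[gene.chrom] = seq[:gs] + take + seq[ge:]
    return Reference(chrom_seqs=chrom_seqs, genes=genes)


@dataclass
class _ReadPlan:
    read_id: str
    klass: str
    gene: Gene
    s_off: int  # aligned sense interval start
    e_off: int
    soft_prefix: str  # adapter bases soft-clipped in the untrimmed alignment
    tail_len: int
    trim_point: int  # read offset the detector trims at (0 = untrimmed class)
    tail_call_pass: bool
    low_quality: bool
    mapq: int
    novel_cluster_id: str = ""


@dataclass
class SimResult:
    reads: list[Read]
    truth: pd.DataFrame
    untrimmed_sam: str
    trimmed_sam: str
    polya_tsv: str
    config: SimConfig


def _sam_header(ref: Reference) -> str:
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom, seq in ref.chrom_seqs.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


def _sam_record(
    plan: _ReadPlan, seq: str, qual: str, trimmed: bool
) -> str:
    gene = plan.gene
    s_off = plan.s_off
    soft_prefix = plan.soft_prefix
    if trimmed:
        if soft_prefix:  # genuine adapter: trimming shortens the clip
            soft_prefix = soft_prefix[plan.trim_point :]
        else:  # decoy: trimmed bases were genomic
            s_off = plan.s_off + plan.trim_point
    pieces = sense_to_genomic_intervals(gene, s_off, plan.e_off)
    ops = []
    prev_end = None
    for gs, ge in pieces:
        if prev_end is not None and gs > prev_end:
            ops.append(f"{gs - prev_end}N")
        ops.append(f"{ge - gs}M")
        prev_end = ge
    lead_clip = len(soft_prefix) if gene.strand == "+" else plan.tail_len
    trail_clip = plan.tail_len if gene.strand == "+" else len(soft_prefix)
    cigar = (
        (f"{lead_clip}S" if lead_clip else "")
        + "".join(ops)
        + (f"{trail_clip}S" if trail_clip else "")
    )
    flag = 0 if gene.strand == "+" else 16
    sam_seq = seq if gene.strand == "+" else _revcomp(seq)
    sam_qual = qual if gene.strand == "+" else qual[::-1]
    return "\t".join(
        [
            plan.read_id,
            str(flag),
            gene.chrom,
            str(pieces[0][0] + 1),
            str(plan.mapq),
            cigar,
            "*",
            "0",
            "0",
            sam_seq,
            sam_qual,
        ]
    )


def simulate_reads(config: SimConfig, reference: Reference) -> SimResult:
    """Simulate the read set, truth table, truth-based SAM pair
    (untrimmed + trimmed) and the signal-domain poly(A) tail table.

    Planted classes are separable at substitution_rate=0: reads without
    a planted adapter are rejection-sampled so their 5' window stays
    below the detection identity threshold, making stage counts equal
    truth counts exactly in the error-free limit.
    """
    rng = np.random.default_rng(config.seed + 1)
    adapter = config.adapter_seq
    det_cfg = AdapterConfig(
        identity_threshold=config.identity_threshold, full_adapter_seq=adapter
    )
    trim_point = adapter.find(det_cfg.barcode_seq) + len(det_cfg.barcode_seq)
    normal_genes = [g for g in reference.genes if not g.is_decoy]
    decoy_genes = [g for g in reference.genes if g.is_decoy]

    n = config.n_reads
    counts = {
        "capped": int(round(config.frac_capped * n)),
        "truncated": int(round(config.frac_truncated * n)),
        "decoy": int(round(config.frac_decoy * n)),
        "degradation_tailed": int(round(config.frac_degradation_tailed * n)),
    }
    counts["uncapped"] = n - sum(counts.values())
    if counts["uncapped"] < 0:
        raise ValueError("class fractions leave no room for uncapped reads")
    classes = [k for k, c in counts.items() for _ in range(c)]
    rng.shuffle(classes)

    plans: list[_ReadPlan] = []

    expression = rng.lognormal(0.0, config.expression_sigma, len(normal_genes))
    expression /= expression.sum()

    def draw_gene() -> Gene:
        return normal_genes[int(rng.choice(len(normal_genes), p=expression))]

    def draw_mapq() -> int:
        u = rng.random()
        if u < config.frac_mapq0:
            return 0
        if u < config.frac_mapq0 + config.frac_mapq_mid:
            return int(rng.integers(1, 60))
        return 60

    def draw_tail() -> int:
        return int(rng.integers(*config.polya_length, endpoint=True))

    def adapterless_start_ok(gene: Gene, s_off: int) -> bool:
        prefix = reference.transcript_seq(gene)[s_off : s_off + det_cfg.search_window]
        identity, _, _ = adapter_identity(prefix, det_cfg)
        return identity < config.identity_threshold

    for i, klass in enumerate(classes):
        read_id = f"read{i:05d}"
        tail_len = draw_tail()
        low_q = rng.random() < config.frac_low_quality
        tail_pass = rng.random() >= config.tail_call_fail_rate
        mapq = draw_mapq()
        if klass == "decoy":
            gene = decoy_genes[int(rng.integers(len(decoy_genes)))]
            plans.append(
                _ReadPlan(read_id, klass, gene, 0, gene.length, "", tail_len,
                          trim_point, tail_pass, low_q, mapq)
            )
            continue
        if klass in ("capped", "degradation_tailed"):
            gene = draw_gene()
            if klass == "capped":
                e_off = gene.length
            else:
                hi = gene.length - config.degradation_min_internal
                e_off = int(rng.integers(max(60, hi // 2), max(61, hi)))
            plans.append(
                _ReadPlan(read_id, klass, gene, 0, e_off, adapter, tail_len,
                          trim_point, tail_pass, low_q, mapq)
            )
            continue
        # adapterless classes: rejection-sample a start whose 5' window
        # cannot trip the detector in the error-free limit
        for _attempt in range(50):
            gene = draw_gene()
            if klass == "uncapped":
                s_off = 0
            else:  # truncated: uniform internal breakpoint, >=50 nt remain
                s_off = int(rng.integers(20, gene.length - 50))
            if adapterless_start_ok(gene, s_off):
                break
        else:
            raise RuntimeError("could not sample an adapter-free read start")
        plans.append(
            _ReadPlan(read_id, klass, gene, s_off, gene.length, "", tail_len,
                      0, tail_pass, low_q, mapq)
        )

    plans.extend(_plan_novel(config, reference, rng, normal_genes, trim_point))

    # materialize sequences, substitutions, qualities
    reads: list[Read] = []
    truth_rows = []
    untrimmed_records = []
    trimmed_records = []
    polya_rows = []
    for plan in plans:
        core = reference.transcript_seq(plan.gene)[plan.s_off : plan.e_off]
        template = plan.soft_prefix + core + "A" * plan.tail_len
        seq = np.array(list(template))
        n_subs = 0
        if config.substitution_rate > 0:
            hit = rng.random(seq.size) < config.substitution_rate
            n_subs = int(hit.sum())
            if n_subs:
                alphabet = "ACGT"
                originals = seq[hit]
                replacements = [
                    alphabet[(alphabet.index(b) + int(rng.integers(1, 4))) % 4]
                    for b in originals
                ]
                seq[hit] = replacements
        sequence = "".join(seq)
        if plan.low_quality:
            quals = rng.integers(2, 7, size=len(sequence))
        else:
            quals = rng.integers(7, 21, size=len(sequence))
        quals = [int(q) for q in quals]
        reads.append(Read(plan.read_id, sequence, quals))
        qual_str = "".join(chr(q + 33) for q in quals)
        untrimmed_records.append(_sam_record(plan, sequence, qual_str, trimmed=False))
        if plan.trim_point:
            trimmed_records.append(
                _sam_record(
                    plan, sequence[plan.trim_point :], qual_str[plan.trim_point :],
                    trimmed=True,
                )
            )
        else:
            trimmed_records.append(_sam_record(plan, sequence, qual_str, trimmed=False))
        if plan.tail_len and plan.tail_call_pass:
            polya_rows.append((plan.read_id, round(plan.tail_len + 0.5, 2), "PASS"))
        elif plan.tail_len and rng.random() < 0.5:
            polya_rows.append((plan.read_id, round(plan.tail_len + 0.5, 2), "NOREGION"))
        # else: absent from the table entirely (closed-world failure)
        g = plan.gene
        p5 = sense_to_genomic_pos(g, plan.s_off)
        p3 = sense_to_genomic_pos(g, plan.e_off - 1)
        truth_rows.append(
            {
                "read_id": plan.read_id,
                "class": plan.klass,
                "transcript_id": g.transcript_id,
                "gene_id": g.gene_id,
                "gene_type": g.gene_type,
                "chrom": g.chrom,
                "strand": g.strand,
                "true_5p": p5,
                "true_3p": p3,
                "adapter_present": bool(plan.soft_prefix) or plan.klass == "decoy",
                "tail_length": plan.tail_len,
                "tail_call_pass": plan.tail_call_pass,
                "low_quality": plan.low_quality,
                "mapq": plan.mapq,
                "novel_cluster_id": plan.novel_cluster_id,
                "n_substitutions": n_subs,
                "read_length": len(sequence),
            }
        )

    header = _sam_header(reference)
    polya_tsv = "readname\tpolya_length\tqc_tag\n" + "".join(
        f"{r}\t{l}\t{t}\n" for r, l, t in polya_rows
    )
    return SimResult(
        reads=reads,
        truth=pd.DataFrame(truth_rows),
        untrimmed_sam=header + "\n".join(untrimmed_records) + "\n",
        trimmed_sam=header + "\n".join(trimmed_records) + "\n",
        polya_tsv=polya_tsv,
        config=config,
    )


def _plan_novel(config, reference, rng, normal_genes, trim_point):
    """Plant novel-TSS read groups: cap-adapted reads whose 5' ends sit
    >= novel_min_dist from every same-strand annotated TSS, clustered
    within 25 nt; distinct groups on one chromosome/strand are kept
    >120 nt apart so single-linkage at 50 nt cannot merge them."""
    plans: list[_ReadPlan] = []
    n_groups = config.n_novel_clusters + config.n_novel_singletons
    if n_groups == 0:
        return plans
    adapter = config.adapter_seq
    tss_by_key: dict[tuple[str, str], list[int]] = {}
    for g in reference.genes:
        tss_by_key.setdefault((g.chrom, g.strand), []).append(g.tss_pos)
    used_by_key: dict[tuple[str, str], list[int]] = {}
    counter = 0
    for gidx in range(n_groups):
        is_singleton = gidx >= config.n_novel_clusters
        size = 1 if is_singleton else int(
            rng.integers(*config.novel_cluster_size, endpoint=True)
        )
        for _attempt in range(500):
            gene = normal_genes[int(rng.integers(len(normal_genes)))]
            if gene.length < 120:
                continue
            # keep the whole group inside one exon (sense domain), so an
            # intron cannot spread the genomic positions apart
            exon_bounds = []
            walked = 0
            exons = gene.exons if gene.strand == "+" else list(reversed(gene.exons))
            for gs, ge in exons:
                exon_bounds.append((walked, walked + (ge - gs)))
                walked += ge - gs
            wide = [(a, b) for a, b in exon_bounds if b - a >= 100]
            if not wide:
                continue
            lo, hi = wide[int(rng.integers(len(wide)))]
            base = int(rng.integers(lo + 30, hi - 60))
            offs = sorted(
                int(base + rng.integers(0, 26)) for _ in range(size)
            )
            positions = [sense_to_genomic_pos(gene, o) for o in offs]
            key = (gene.chrom, gene.strand)
            if any(
                min(abs(p - t) for t in tss_by_key[key]) < config.novel_min_dist
                for p in positions
            ):
                continue
            if any(
                abs(p - u) <= 120
                for p in positions
                for u in used_by_key.get(key, [])
            ):
                continue
            used_by_key.setdefault(key, []).extend(positions)
            cluster_id = (
                f"singleton{gidx - config.n_novel_clusters:03d}"
                if is_singleton
                else f"cluster{gidx:03d}"
            )
            for off in offs:
                plans.append(
                    _ReadPlan(
                        read_id=f"novel{counter:05d}",
                        klass="capped",
                        gene=gene,
                        s_off=off,
                        e_off=gene.length,
                        soft_prefix=adapter,
                        tail_len=int(rng.integers(*config.polya_length, endpoint=True)),
                        trim_point=trim_point,
                        tail_call_pass=True,
                        low_quality=False,
                        mapq=60,
                        novel_cluster_id=cluster_id,
                    )
                )
                counter += 1
            break
        else:
            raise RuntimeError("could not place a novel-TSS group; enlarge the genome")
    return plans


def expected_stage_outcomes(truth: pd.DataFrame) -> pd.DataFrame:
    """Truth-derived cascade expectations in the error-free limit."""
    out = pd.DataFrame({"read_id": truth["read_id"]})
    quality = ~truth["low_quality"]
    cap = quality & truth["adapter_present"]
    confirmed = cap & (truth["class"] != "decoy")
    clip = confirmed  # truth alignments of confirmed reads carry small clips
    tail = clip & truth["tail_call_pass"]
    site = tail & (truth["class"] != "degradation_tailed")
    out["quality_pass"] = quality
    out["cap_adapted"] = cap
    out["true_positive_confirmed"] = confirmed
    out["clip_pass"] = clip
    out["polya_tail_pass"] = tail
    out["polya_site_pass"] = site
    return out


def write_outputs(result: SimResult, reference: Reference, outdir) -> dict[str, str]:
    """Write FASTA/GTF/BED/FASTQ/SAM/TSV + truth.tsv; deterministic bytes."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def path(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    with open(path("genome.fa"), "w") as fh:
        for chrom, seq in reference.chrom_seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(path("annotation.gtf"), "w") as fh:
        for g in reference.genes:
            span_s, span_e = g.span
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.transcript_id}"; '
                f'gene_name "{g.gene_name}"; gene_type "{g.gene_type}";'
            )
            for feature, (s, e) in [("gene", g.span), ("transcript", g.span)] + [
                ("exon", ex) for ex in g.exons
            ]:
                fh.write(
                    f"{g.chrom}\tsim\t{feature}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    with open(path("polya_sites.bed"), "w") as fh:
        for g in reference.genes:
            fh.write(
                f"{g.chrom}\t{g.tes_pos}\t{g.tes_pos + 1}\t{g.transcript_id}\t0\t{g.strand}\n"
            )
    write_fastq(result.reads, path("reads.fastq"))
    with open(path("untrimmed.sam"), "w") as fh:
        fh.write(result.untrimmed_sam)
    with open(path("trimmed.sam"), "w") as fh:
        fh.write(result.trimmed_sam)
    with open(path("polya_table.tsv"), "w") as fh:
        fh.write(result.polya_tsv)
    result.truth.to_csv(path("truth.tsv"), sep="\t", index=False)
    return paths
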