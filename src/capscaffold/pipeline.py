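"""End-to-end orchestration: detect -> filter -> call -> novel-TSS -> summarize.

Thresholds live in a flat key/value config whose defaults are the
published operating point: q_min=7, identity=74, clip_remove=15 (remove
>= 15, keep <= 14), novel_dist=300, link=50, merge=25,
polya_window=(-60, 10), fl5=25, fl3=50, race_window=100.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import adapter_detection, alignment_filters, io_formats, scaffold_caller, tss_analysis

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]


@dataclass
class PipelineConfig:
    q_min: float = 7.0
    identity_threshold: float = 74.0
    search_window: int = 150
    clip_remove: int = 15
    novel_dist: int = 300
    link_dist: int = 50
    merge_window: int = 25
    polya_window: tuple[int, int] = (-60, 10)
    fl5: int = 25
    fl3: int = 50
    race_window: int = 100
    min_novel_reads: int = 2

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = dict(mapping)
        if "polya_window" in cfg:
            cfg["polya_window"] = tuple(cfg["polya_window"])
        return cls(**cfg)


@dataclass
class PipelineResult:
    calls: list  # per-read ScaffoldCall
    funnel: pd.DataFrame
    adapter_calls: list
    confirmed_ids: set
    novel_clusters: list
    dropped_reasons: dict
    stage_read_ids: dict[str, list[str]] = field(default_factory=dict)

    def funnel_report(self) -> dict:
        report = {"stages": self.funnel.to_dict(orient="records")}
        report["n_novel_clusters"] = len(self.novel_clusters)
        report["n_novel_tss_reads"] = sum(c.size for c in self.novel_clusters)
        report["true_positive_drops"] = self.dropped_reasons
        return report


def run_all(
    fastq_path,
    untrimmed_sam_path,
    trimmed_sam_path,
    polya_tsv_path,
    gtf_path,
    polya_bed_path,
    config: PipelineConfig | None = None,
    outdir=None,
) -> PipelineResult:
    """Run the full cascade from files to per-read verdicts.

    Missing inputs fail before any stage runs.  When ``outdir`` is
    given, persists the per-stage read-id sets, the verdict table, the
    funnel report (counts plus both percentage bases) and the novel-TSS
    cluster BED.
    """
    config = config or PipelineConfig()
    for path in (fastq_path, untrimmed_sam_path, trimmed_sam_path,
                 polya_tsv_path, gtf_path, polya_bed_path):
        if not os.path.exists(path):
            raise FileNotFoundError(f"missing pipeline input: {path}")

    reads = list(io_formats.read_fastq(fastq_path))
    reads = [
        io_formats.Read(r.read_id, io_formats.u_to_t(r.sequence), r.qualities)
        for r in reads
    ]
    annotation = io_formats.load_gtf_annotation(gtf_path)
    polya_index = io_formats.load_bed_sites(polya_bed_path)
    polya_table = io_formats.load_polya_table(polya_tsv_path)

    adapter_cfg = adapter_detection.AdapterConfig(
        identity_threshold=config.identity_threshold,
        search_window=config.search_window,
    )
    adapter_calls = []
    quality_pass_ids = set()
    for read in reads:
        if read.mean_q >= config.q_min:
            quality_pass_ids.add(read.read_id)
        call, _trimmed = adapter_detection.classify_and_trim(read, adapter_cfg)
        adapter_calls.append(call)

    untrimmed = alignment_filters.select_primary(
        alignment_filters.read_sam(untrimmed_sam_path)
    )
    trimmed = alignment_filters.select_primary(
        alignment_filters.read_sam(trimmed_sam_path)
    )
    detected_ids = {
        c.read_id for c in adapter_calls
        if c.detected and c.read_id in quality_pass_ids
    }
    confirmed_ids, dropped = alignment_filters.true_positive_filter(
        detected_ids, untrimmed, trimmed, clip_remove=config.clip_remove
    )

    trimmed_by_id = {a.read_id: a for a in trimmed}
    confirmed_alns = [
        trimmed_by_id[rid] for rid in sorted(confirmed_ids) if rid in trimmed_by_id
    ]
    clip_pass = alignment_filters.clip_filter(confirmed_alns, config.clip_remove)
    novel_clusters = tss_analysis.find_novel_tss(
        clip_pass,
        annotation,
        min_dist=config.novel_dist,
        link_dist=config.link_dist,
        min_reads=config.min_novel_reads,
    )
    novel_ids = {rid for c in novel_clusters for rid in c.member_read_ids}

    calls = scaffold_caller.call_scaffolds(
        reads,
        adapter_calls,
        confirmed_ids,
        trimmed,
        polya_table,
        polya_index,
        annotation,
        q_min=config.q_min,
        clip_remove=config.clip_remove,
        polya_window=config.polya_window,
        novel_tss_ids=novel_ids,
    )
    funnel = scaffold_caller.funnel_counts(calls)
    stage_ids = {
        stage: sorted(c.read_id for c in calls if c.stages[stage])
        for stage in scaffold_caller.STAGES
    }
    result = PipelineResult(
        calls=calls,
        funnel=funnel,
        adapter_calls=adapter_calls,
        confirmed_ids=confirmed_ids,
        novel_clusters=novel_clusters,
        dropped_reasons=dropped,
        stage_read_ids=stage_ids,
    )
    if outdir is not None:
        _persist(result, config, outdir)
    return result


def _persist(result: PipelineResult, config: PipelineConfig, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    result.funnel.to_csv(os.path.join(outdir, "funnel.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "funnel.json"), "w") as fh:
        json.dump(
            {"config": asdict(config), **result.funnel_report()},
            fh, indent=2, default=str,
        )
        fh.write("\n")
    verdicts = pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                **c.stages,
                "is_full_length": c.is_full_length,
                "is_novel_tss": c.is_novel_tss,
                "gene_id": c.gene_id or "",
                "gene_type": c.gene_type or "",
                "mapq": -1 if c.mapq is None else c.mapq,
                "polya_site_distance": (
                    "" if c.polya_site_distance is None else c.polya_site_distance
                ),
            }
            for c in result.calls
        ]
    )
    verdicts.to_csv(os.path.join(outdir, "verdicts.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "stage_read_ids.json"), "w") as fh:
        json.dump(result.stage_read_ids, fh, indent=0)
        fh.write("\n")
    with open(os.path.join(outdir, "novel_tss_clusters.bed"), "w") as fh:
        for c in result.novel_clusters:
            fh.write(
                f"{c.chrom}\t{c.representative_pos}\t{c.representative_pos + 1}"
                f"\tsize={c.size}\t{c.size}\t{c.strand}\n"
            )
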