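import pandas as pd
import pytest

from capscaffold.alignment_filters import AlignedRead
from capscaffold.io_formats import (
    AnnotationIndex,
    PolyASiteIndex,
    PolyATailTable,
    Read,
    Transcript,
)
from capscaffold.adapter_detection import AdapterCall
from capscaffold.scaffold_caller import (
    STAGES,
    call_scaffolds,
    classify_gene_type,
    correlate_cpm,
    full_length_untreated,
    funnel_counts,
    gene_counts_cpm,
    mapq_summary,
    polya_site_distance,
    polya_site_filter,
)


def _tx(chrom="chr1", strand="+", tss=1000, tes=2000, tid="T1", gid="G1",
        gtype="protein_coding"):
    return Transcript(chrom, strand, tss, tes, tid, gid, gid, gtype)


def _aln(read_id="r", chrom="chr1", strand="+", start=100, end=200,
         cigar=None, mapq=60):
    cigar = cigar or f"{end - start}M"
    flags = 0 if strand == "+" else 16
    return AlignedRead(read_id, chrom, strand, start, end, cigar, mapq, flags)


def _aln_with_3p(pos, strand="+", read_id="r"):
    if strand == "+":
        return _aln(read_id, start=pos - 99, end=pos + 1, strand=strand)
    return _aln(read_id, start=pos, end=pos + 100, strand=strand)


class TestPolyASiteDistance:
    def test_exact_site_is_zero(self):
        idx = PolyASiteIndex([("chr1", "+", 2000)])
        assert polya_site_distance(_aln_with_3p(2000), idx) == 0

    def test_upstream_on_plus_is_negative(self):
        idx = PolyASiteIndex([("chr1", "+", 2000)])
        assert polya_site_distance(_aln_with_3p(1940), idx) == -60

    def test_minus_strand_downstream_is_positive(self):
        # genomically left of a minus-strand site = downstream = +10
        idx = PolyASiteIndex([("chr1", "-", 2000)])
        assert polya_site_distance(_aln_with_3p(1990, strand="-"), idx) == +10

    def test_no_site_on_strand_is_undefined(self):
        idx = PolyASiteIndex([("chr1", "-", 2000)])
        assert polya_site_distance(_aln_with_3p(2000, strand="+"), idx) is None


class TestPolyASiteFilter:
    @pytest.mark.parametrize(
        "d,expected",
        [(-60, True), (-61, False), (10, True), (11, False), (0, True),
         (None, False)],
    )
    def test_window_boundaries_inclusive(self, d, expected):
        assert polya_site_filter(d) is expected


class TestFullLengthUntreated:
    def _ann(self):
        return AnnotationIndex([_tx(tss=1000, tes=2000)])

    def test_exact_match(self):
        assert full_length_untreated(_aln(start=1000, end=2001), self._ann())

    def test_boundaries_inclusive(self):
        # 5' delta 25, 3' delta 50 -> true
        assert full_length_untreated(_aln(start=1025, end=2051), self._ann())
        # 5' delta 26 -> false even with perfect 3'
        assert not full_length_untreated(_aln(start=1026, end=2001), self._ann())


class TestGeneTypeAndCpm:
    def test_gene_type_fractions(self):
        ann = AnnotationIndex(
            [
                _tx(tss=1000, tes=2000, tid="T1", gid="G1", gtype="protein_coding"),
                _tx(tss=9000, tes=9500, tid="T2", gid="G2", gtype="Mt_rRNA"),
            ]
        )
        reads = [
            _aln("r1", start=1000, end=1500),
            _aln("r2", start=1010, end=1500),
            _aln("r3", start=990, end=1500),
            _aln("r4", start=9000, end=9100),
        ]
        fractions = classify_gene_type(reads, ann)
        assert fractions["protein_coding"] == pytest.approx(0.75)
        assert fractions["Mt_rRNA"] == pytest.approx(0.25)

    def test_empty_input_no_division_by_zero(self):
        assert len(classify_gene_type([], AnnotationIndex([]))) == 0

    def test_cpm_single_gene(self):
        cpm = gene_counts_cpm({"G1": 5})
        assert cpm["G1"] == pytest.approx(1_000_000)

    def test_identical_tables_rho_one(self):
        a = gene_counts_cpm({"G1": 5, "G2": 10, "G3": 2})
        assert correlate_cpm(a, a) == pytest.approx(1.0)

    def test_anti_ordered_rho_minus_one(self):
        a = gene_counts_cpm({"G1": 1, "G2": 2, "G3": 3})
        b = gene_counts_cpm({"G1": 3, "G2": 2, "G3": 1})
        assert correlate_cpm(a, b) == pytest.approx(-1.0)

    def test_union_of_genes_with_absent_as_zero(self):
        a = gene_counts_cpm({"G1": 5, "G2": 5})
        b = gene_counts_cpm({"G2": 5, "G3": 5})
        rho = correlate_cpm(a, b)
        assert -1.0 <= rho < 1.0


class TestMapqSummary:
    def test_all_q60(self):
        s = mapq_summary([60, 60, 60])
        assert s.q60_fraction == 1.0 and s.q0_fraction == 0.0

    def test_even_split(self):
        s = mapq_summary([0, 60])
        assert s.q0_fraction == 0.5 and s.q60_fraction == 0.5
        assert s.histogram.sum() == 2

    def test_empty(self):
        s = mapq_summary([])
        assert s.q0_fraction == 0.0 and s.n == 0


class TestCallScaffolds:
    def _inputs(self):
        ann = AnnotationIndex([_tx(tss=1000, tes=2000)])
        sites = PolyASiteIndex([("chr1", "+", 2000)])
        reads = [Read(f"r{i}", "ACGT" * 25, [12] * 100) for i in range(1, 4)]
        calls = [
            AdapterCall("r1", True, 100.0, 0, 42, 58),
            AdapterCall("r2", True, 100.0, 0, 42, 58),
            AdapterCall("r3", False, 40.0, 3, 9, 100),
        ]
        alns = [
            _aln("r1", start=1000, end=2001, cigar="3S998M"),
            _aln("r2", start=1000, end=1800, cigar="3S797M"),  # 3' internal
            _aln("r3", start=1500, end=2001),
        ]
        table = PolyATailTable({"r1": (55.0, "PASS"), "r2": (40.0, "PASS")})
        return reads, calls, alns, table, sites, ann

    def test_planted_full_length_passes_all_stages(self):
        reads, calls, alns, table, sites, ann = self._inputs()
        out = call_scaffolds(reads, calls, {"r1", "r2"}, alns, table, sites, ann)
        by_id = {c.read_id: c for c in out}
        assert by_id["r1"].is_full_length
        assert all(by_id["r1"].stages[s] for s in STAGES)

    def test_degradation_tailed_fails_site_filter(self):
        reads, calls, alns, table, sites, ann = self._inputs()
        out = call_scaffolds(reads, calls, {"r1", "r2"}, alns, table, sites, ann)
        by_id = {c.read_id: c for c in out}
        assert by_id["r2"].stages["polya_tail_pass"]
        assert not by_id["r2"].stages["polya_site_pass"]
        assert by_id["r2"].polya_site_distance == -201

    def test_missing_tail_entry_fails_tail_filter(self):
        reads, calls, alns, _, sites, ann = self._inputs()
        table = PolyATailTable({})  # closed world: nobody has tail evidence
        out = call_scaffolds(reads, calls, {"r1", "r2"}, alns, table, sites, ann)
        assert not any(c.stages["polya_tail_pass"] for c in out)

    def test_undetected_read_fails_cap_stage_only(self):
        reads, calls, alns, table, sites, ann = self._inputs()
        out = call_scaffolds(reads, calls, {"r1", "r2"}, alns, table, sites, ann)
        by_id = {c.read_id: c for c in out}
        assert by_id["r3"].stages["quality_pass"]
        assert not by_id["r3"].stages["cap_adapted"]
        assert not by_id["r3"].is_full_length

    def test_funnel_monotone_and_percentages_recompute(self):
        reads, calls, alns, table, sites, ann = self._inputs()
        out = call_scaffolds(reads, calls, {"r1", "r2"}, alns, table, sites, ann)
        funnel = funnel_counts(out)
        counts = funnel["count"].tolist()
        assert counts == sorted(counts, reverse=True)
        total = counts[0]
        for _, row in funnel.iterrows():
            assert row["pct_of_treated"] == pytest.approx(
                100 * row["count"] / total
            )


class TestFunnelOnSimulation:
    def test_disabling_filters_returns_quality_pass_set(self, sim_small,
                                                        sim_small_pipeline):
        # identity limit: with thresholds wide open every quality-pass,
        # adapter-bearing, aligned, tabled read flows through
        funnel = sim_small_pipeline.funnel
        assert funnel["count"].is_monotonic_decreasing

    def test_mapq_summary_matches_truth(self, sim_small, sim_small_pipeline):
        truth = sim_small["result"].truth
        full = [c for c in sim_small_pipeline.calls if c.is_full_length]
        got = mapq_summary([c.mapq for c in full])
        want = truth.set_index("read_id").loc[[c.read_id for c in full], "mapq"]
        assert got.q60_fraction == pytest.approx((want == 60).mean())
        assert got.q0_fraction == pytest.approx((want == 0).mean())
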