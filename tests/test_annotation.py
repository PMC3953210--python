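"""Breakpoint localization, fusion prediction, cytobands and karyotypes."""

import warnings

import pytest

from matesv.annotation import (
    GeneIndex,
    GeneModel,
    band_for_position,
    karyotype_string,
    load_cytobands,
    locate_breakpoint,
    predict_fusions,
)
from matesv.calling import InsertStats, clusters_from_breakpoints, type_svs

STATS = InsertStats.from_median(5000)


def make_gene(gene_id="G", chrom="chr1", strand="+", exons=((100, 200), (300, 400)),
              biotype="protein_coding", name=None):
    return GeneModel(gene_id=gene_id, gene_name=name or gene_id, chrom=chrom,
                     strand=strand, start=exons[0][0], end=exons[-1][1],
                     exons=tuple(exons), biotype=biotype)


def evenly_spaced_gene(gene_id, chrom, strand, start, n_exons,
                       exon_len=100, intron_len=900):
    exons = [(start + i * (exon_len + intron_len),
              start + i * (exon_len + intron_len) + exon_len - 1)
             for i in range(n_exons)]
    return make_gene(gene_id, chrom, strand, exons)


class TestLocateBreakpoint:
    def test_intron_and_exon_on_plus_strand(self):
        idx = GeneIndex([make_gene()])
        assert locate_breakpoint(("chr1", 250), idx).region == "intron1"
        assert locate_breakpoint(("chr1", 150), idx).region == "exon1"

    def test_minus_strand_numbering_is_transcript_order(self):
        idx = GeneIndex([make_gene(strand="-")])
        ann = locate_breakpoint(("chr1", 250), idx)
        assert ann.region == "intron1"  # between 3'-most genomic exon (exon1) and exon2
        assert locate_breakpoint(("chr1", 150), idx).region == "exon2"
        assert locate_breakpoint(("chr1", 350), idx).region == "exon1"

    def test_intergenic_with_distance(self):
        idx = GeneIndex([make_gene()])
        ann = locate_breakpoint(("chr1", 1000), idx)
        assert ann.intergenic and ann.region == "intergenic"
        assert ann.distance == 600
        assert ann.region_kind == "downstream"  # past the 3' end of a + gene

    def test_overlapping_genes_primary_is_longest(self):
        long_g = make_gene("LONG", exons=((50, 120), (300, 800)))
        short_g = make_gene("SHORT", exons=((280, 320), (340, 380)))
        ann = locate_breakpoint(("chr1", 330), idx := GeneIndex([short_g, long_g]))
        assert ann.gene.gene_id == "LONG"
        assert {g.gene_id for g in ann.overlapping_genes} == {"LONG", "SHORT"}

    def test_strand_mirror_consistency(self):
        # a minus-strand gene with mirrored exon layout labels the mirrored
        # breakpoint identically to the original plus-strand gene
        exons = ((100, 200), (400, 450), (600, 900))
        lo, hi = 100, 900
        mirrored = tuple(sorted((lo + hi - e, lo + hi - s) for s, e in exons))
        plus = GeneIndex([make_gene("P", strand="+", exons=exons)])
        minus = GeneIndex([make_gene("M", strand="-", exons=mirrored)])
        for bp in range(100, 901, 7):
            a = locate_breakpoint(("chr1", bp), plus)
            b = locate_breakpoint(("chr1", lo + hi - bp), minus)
            assert a.region == b.region


class TestFusionPrediction:
    def _reciprocal_call(self, bpA, bpB):
        clusters = clusters_from_breakpoints(
            "reciprocal_translocation", "chrA", bpA, "chrB", bpB)
        calls = type_svs(clusters, {}, STATS)
        assert calls[0].sv_type == "reciprocal_translocation"
        return calls[0]

    def test_reciprocal_yields_both_products(self):
        # 43-exon gene A broken in intron 1, 8-exon gene B broken in intron 7,
        # both transcribed toward the junctions: the two derivatives produce
        # the two reciprocal fusion transcripts
        a = evenly_spaced_gene("A", "chrA", "+", start=10_000, n_exons=43)
        b = evenly_spaced_gene("B", "chrB", "+", start=20_000, n_exons=8)
        bpA = 10_000 + 100 + 450          # inside intron 1 of A
        bpB = 20_000 + 7 * 1000 - 450     # inside intron 7 of B
        idx = GeneIndex([a, b])
        assert locate_breakpoint(("chrA", bpA), idx).region == "intron1"
        assert locate_breakpoint(("chrB", bpB), idx).region == "intron7"
        fusions = predict_fusions(self._reciprocal_call(bpA, bpB), idx)
        assert {f.label for f in fusions} == {"Aex1_Bex8", "Bex1-7_Aex2-43"}
        by_label = {f.label: f for f in fusions}
        assert by_label["Aex1_Bex8"].five_prime_exons == (1, 1)
        assert by_label["Aex1_Bex8"].three_prime_exons == (8, 8)
        assert by_label["Bex1-7_Aex2-43"].five_prime_exons == (1, 7)
        assert by_label["Bex1-7_Aex2-43"].three_prime_exons == (2, 43)

    def test_inversion_with_cotranscribed_genes_yields_no_fusion(self):
        # both genes on the same strand transcribe toward each other once one
        # of them is inverted: no fusion mRNA can result
        g1 = evenly_spaced_gene("G1", "chr2", "+", start=10_000, n_exons=5)
        g2 = evenly_spaced_gene("G2", "chr2", "+", start=300_000, n_exons=4)
        clusters = clusters_from_breakpoints("inversion", "chr2", 11_500, "chr2", 301_500)
        call = type_svs(clusters, {"chr2": (100_000, 110_000)}, STATS)[0]
        assert predict_fusions(call, GeneIndex([g1, g2])) == []

    def test_inversion_with_opposite_strand_genes_fuses(self):
        g1 = evenly_spaced_gene("G1", "chr2", "+", start=10_000, n_exons=5)
        g2 = evenly_spaced_gene("G2", "chr2", "-", start=300_000, n_exons=4)
        clusters = clusters_from_breakpoints("inversion", "chr2", 11_500, "chr2", 301_500)
        call = type_svs(clusters, {"chr2": (100_000, 110_000)}, STATS)[0]
        fusions = predict_fusions(call, GeneIndex([g1, g2]))
        assert len(fusions) == 2  # both inversion junctions are productive

    def test_intergenic_side_yields_no_fusion(self):
        a = evenly_spaced_gene("A", "chrA", "+", start=10_000, n_exons=3)
        idx = GeneIndex([a])
        call = self._reciprocal_call(10_000 + 100 + 450, 500_000)
        assert predict_fusions(call, idx) == []

    @pytest.mark.parametrize("sA,sB,expected", [
        ("+", "+", {"Aex1_Bex5-8", "Bex1-4_Aex2-5"}),
        ("-", "-", {"Bex1-4_Aex5", "Aex1-4_Bex5-8"}),
        ("+", "-", set()),
        ("-", "+", set()),
    ])
    def test_translocation_orientation_oracle(self, sA, sB, expected):
        """Emission matches the hand adjacency rule: fusion iff strands equal.

        Breakpoints sit after genomic exon 1 of the 5-exon gene A (intron 1
        if A is '+', intron 4 if '-') and after genomic exon 4 of the 8-exon
        gene B (intron 4 either way).  On the derivative keeping (A-left,
        B-right), two '+' genes read A->B; two '-' genes read B->A on the
        minus strand; opposite strands transcribe toward/away from each
        other, so nothing is emitted.
        """
        a = evenly_spaced_gene("A", "chrA", sA, start=10_000, n_exons=5)
        b = evenly_spaced_gene("B", "chrB", sB, start=20_000, n_exons=8)
        bpA = 10_000 + 100 + 450       # genomic gap after exon 1 of A
        bpB = 20_000 + 4 * 1000 - 450  # genomic gap after exon 4 of B
        idx = GeneIndex([a, b])
        fusions = predict_fusions(self._reciprocal_call(bpA, bpB), idx)
        assert {f.label for f in fusions} == expected


class TestBandsAndKaryotype:
    @pytest.fixture
    def bands(self, tmp_path):
        path = tmp_path / "cytoBand.txt"
        path.write_text(
            "chr2\t0\t5000\tp25.1\tgneg\n"
            "chr2\t5000\t10000\tq33\tgpos50\n"
            "chr7\t0\t5000\tp1\tgneg\n"
            "chr7\t5000\t10000\tq33\tgpos50\n"
            "chr19\t0\t10000\tq13.4\tgneg\n"
        )
        return load_cytobands(path)

    def test_lookup_and_boundary_convention(self, bands):
        assert band_for_position(bands, "chr2", 4000) == "p25.1"
        assert band_for_position(bands, "chr2", 5000) == "p25.1"  # tie to earlier band
        assert band_for_position(bands, "chr2", 5001) == "q33"

    def test_bands_partition_chromosome(self, bands):
        for pos in range(1, 10_001):
            hits = [b for (s, e, b) in bands["chr2"] if s <= pos <= e]
            assert len(hits) == 1
            assert band_for_position(bands, "chr2", pos) == hits[0]

    def test_outside_map_raises(self, bands):
        with pytest.raises(KeyError):
            band_for_position(bands, "chr2", 99_999)
        with pytest.raises(KeyError):
            band_for_position(bands, "chrX", 10)

    def test_tokens(self, bands):
        t = type_svs(clusters_from_breakpoints(
            "reciprocal_translocation", "chr2", 2000, "chr7", 8000), {}, STATS)
        inv = type_svs(clusters_from_breakpoints(
            "inversion", "chr2", 6000, "chr2", 9000),
            {"chr2": (4500, 4800)}, STATS)
        dele = type_svs(clusters_from_breakpoints(
            "deletion", "chr19", 2000, "chr19", 8000), {}, STATS)
        report = karyotype_string(t + inv + dele, bands, base_karyotype="46,XY")
        assert report.tokens == ["t(2;7)(p25.1;q33)", "inv(2)(q33q33)", "del(19)(q13.4)"]
        assert report.karyotype == "46,XY,t(2;7)(p25.1;q33),inv(2)(q33q33),del(19)(q13.4)"

    def test_empty_call_list_leaves_base_karyotype(self, bands):
        report = karyotype_string([], bands, base_karyotype="46,XY")
        assert report.karyotype == "46,XY"

    def test_lookup_failure_degrades_to_coordinates(self, bands):
        calls = type_svs(clusters_from_breakpoints(
            "deletion", "chrX", 2000, "chrX", 8000), {}, STATS)
        with pytest.warns(UserWarning, match="band lookup failed"):
            report = karyotype_string(calls, bands)
        assert report.tokens == ["del(X)(chrX:2000-8000)"]


def test_disrupted_gene_report_rows():
    from matesv.annotation import disrupted_gene_report

    a = evenly_spaced_gene("NUPL", "chrA", "+", start=10_000, n_exons=43)
    b = evenly_spaced_gene("LINCL", "chrB", "+", start=20_000, n_exons=8)
    idx = GeneIndex([a, b])
    calls = type_svs(clusters_from_breakpoints(
        "reciprocal_translocation", "chrA", 10_550, "chrB", 26_550), {}, STATS)
    rows = disrupted_gene_report(calls, idx)
    assert {r["gene"] for r in rows} == {"NUPL", "LINCL"}
    assert all(r["exon_count"] in (43, 8) for r in rows)
    assert any("NUPLex1_LINCLex8" in r["fusion"] for r in rows)
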