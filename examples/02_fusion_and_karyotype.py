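"""Annotate a reciprocal translocation: disrupted genes, fusions, karyotype.

A 43-exon gene on chrA is broken in intron 1 and an 8-exon gene on chrB in
intron 7, both transcribed toward the junctions.  The balanced reciprocal
exchange is predicted to produce the two reciprocal fusion transcripts; the
same breakpoints are also rendered as an ISCN-style karyotype token.
"""

from matesv.annotation import (
    GeneIndex, GeneModel, karyotype_string, load_cytobands, locate_breakpoint,
    predict_fusions,
)
from matesv.calling import InsertStats, clusters_from_breakpoints, type_svs

import pathlib
import tempfile

STATS = InsertStats.from_median(5000)


def gene(gid, chrom, strand, start, n_exons):
    exons = tuple((start + i * 1000, start + i * 1000 + 99) for i in range(n_exons))
    return GeneModel(gene_id=gid, gene_name=gid, chrom=chrom, strand=strand,
                     start=exons[0][0], end=exons[-1][1], exons=exons)


genes = GeneIndex([gene("NUPL", "chrA", "+", 10_000, 43),
                   gene("LINCL", "chrB", "+", 20_000, 8)])
bpA, bpB = 10_500, 26_500

call = type_svs(clusters_from_breakpoints(
    "reciprocal_translocation", "chrA", bpA, "chrB", bpB, support=30), {}, STATS)[0]

for chrom, bp in (("chrA", bpA), ("chrB", bpB)):
    ann = locate_breakpoint((chrom, bp), genes)
    print(f"breakpoint {chrom}:{bp} -> {ann.gene.gene_name} {ann.region} "
          f"({ann.gene.n_exons} exons)")

print("\npredicted fusion transcripts (exon-granularity, frame unknown):")
for f in predict_fusions(call, genes):
    print(f"  {f.label}: 5' {f.five_prime_gene} exons "
          f"{f.five_prime_exons[0]}-{f.five_prime_exons[1]}, "
          f"3' {f.three_prime_gene} exons "
          f"{f.three_prime_exons[0]}-{f.three_prime_exons[1]}")

with tempfile.TemporaryDirectory() as d:
    band_file = pathlib.Path(d) / "cytoBand.txt"
    band_file.write_text("chrA\t0\t25000\tp25.1\tgneg\nchrA\t25000\t60000\tq11\tgpos\n"
                         "chrB\t0\t15000\tp11\tgneg\nchrB\t15000\t40000\tq33\tgpos\n")
    report = karyotype_string([call], load_cytobands(band_file), "46,XY")
print(f"\nrevised karyotype: {report.karyotype}")
print("The token t(A;B)(p25.1;q33) reads: reciprocal translocation between "
      "chromosomes A and B with breakpoints in bands p25.1 and q33.")
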