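"""Library QC and cross-platform validation metrics.

Computes the theoretical spanning read-depth of a genome-wide mate-pair run,
the enrichment fold of a flow-sorted chromosome fraction, and the validation
rate of a predicted call set against an independent confirmation set.
"""

from matesv.calling import InsertStats, clusters_from_breakpoints, type_svs
from matesv.metrics import chromosome_enrichment, spanning_coverage, validate_callsets

STATS = InsertStats.from_median(5000)

# 28.2 million pairs at a 5,012 bp median insert over a ~3.1 Gb genome
cov = spanning_coverage(28_200_000, 5_012, 3_095_700_000)
print(f"spanning read-depth: {cov.spanning_depth:.1f}x "
      f"({cov.n_pairs:,} pairs x {cov.median_insert:,} bp / {cov.genome_size:,} bp)")

counts = {"chr2": 60_000, "chr1": 7_000, "chr3": 5_500}
lengths = {"chr2": 243_000_000, "chr1": 249_000_000, "chr3": 198_000_000}
enr = chromosome_enrichment(counts, lengths, "chr2")
print(f"chr2 enrichment: {enr.fold:.2f}-fold over its length-proportional share "
      f"(observed read fraction {enr.observed_fraction:.2f})")


def deletion(chrom, start, end):
    return type_svs(clusters_from_breakpoints("deletion", chrom, start, chrom, end),
                    {}, STATS)[0]


predicted = [deletion("chr2", 2_000_000 * i, 2_000_000 * i + 60_000)
             for i in range(1, 12)]
confirmed = [deletion("chr2", 2_000_000 * i + 5_000, 2_000_000 * i + 55_000)
             for i in range(1, 11)]
res = validate_callsets(predicted, confirmed, min_reciprocal_overlap=0.5)
print(f"validation: {res.n_confirmed} of {res.n_predicted} predicted SVs "
      f"confirmed -> {res.rate}% (exact {res.rate_exact:.1f}%)")
print("A predicted call is confirmed when a same-type confirmed call covers "
      "it reciprocally by at least 50%.")
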