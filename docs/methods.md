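# Methods

## Model of the data

A mate-pair library circularizes ~5 kb fragments so that a short read pair
samples the two fragment ends. After alignment, a pair is a 6-tuple
(chromA, posA, strandA, chromB, posB, strandB) plus mapping qualities and a
duplicate flag; the library as a whole is characterized by the distribution
of the outer span of concordant pairs. We model the insert length as
log-normal, parameterized by its median *m* and standard deviation *s* and
truncated to [2·read_length, 4·*m*]: long-insert protocols produce
right-skewed, strictly positive insert distributions for which the
log-normal is the standard desk model, and the median is the statistic
protocols actually report. Concordant pairs follow a fixed orientation
convention — default **RF** (reads face outward after circularization),
configurable to FR — and a fraction of pairs are short-insert paired-end
contaminants that escaped circularization enrichment; these carry the
*opposite* orientation convention and a small insert (default 300 bp).

Coordinates are 1-based inclusive everywhere inside the package; BED-family
files are converted to 0-based half-open, and VCF to 1-based, only in the
reader/writer layer.

## Simulator

`apply_sv_plan` applies planted deletions, inversions and reciprocal
translocations, in list order, to a toy reference, maintaining each
derivative as an ordered list of oriented reference segments. This yields an
exact, invertible liftover: every derived base maps to one reference base
(with orientation), and junction indels — up to ±10 bp lost or duplicated on
the derived strand immediately left of a junction — are represented by
trimming or by `inserted`-flagged duplicate segments. Breakpoints of
distinct events must be > 1 kb apart; conflicts are rejected with a full
report.

`simulate_pairs` draws fragments uniformly over the derived genome
(chromosomes weighted by length), assigns insert lengths from the truncated
log-normal, and maps each 36 bp end through the liftover — the simulator
plays the aligner. Reads that would straddle a junction are dropped with
their mate, as a short-read aligner would fail them; this makes
junction-adjacent coverage realistic rather than optimistic. One integer
seed drives a single generator for all stochastic choices.

What the simulator deliberately does **not** model: base-call errors and
quality strings, PCR-duplicate families, repeat-induced multi-mapping, and
chimeric alignment artifacts. Passing recovery tests therefore demonstrate
the correctness of the calling geometry and bookkeeping, not robustness to
alignment noise in repetitive genomes, where mate-pair data are known to
produce false positives that the curation log would have to absorb.

## Calling

* **Insert statistics.** Median outer span of concordantly oriented
  same-chromosome pairs with span < 10× the nominal insert; the cutoff is
  fixed at 2× the median. At least 100 usable pairs are required unless a
  median override is supplied. The MAD of the same spans is kept as the
  library's dispersion estimate.
* **Classification precedence.** duplicate > low_quality (MAPQ < 20, both
  ends) > interchromosomal > long_span > orientation_aberrant > concordant.
  The classes are mutually exclusive and the function is total; pair end
  order never matters because ends are canonicalized by (chromosome,
  position) with natural chromosome sort.
* **Clustering.** Single linkage within each signature (chromosome pair +
  strand pair): two pairs link iff both end positions agree within the
  cutoff. Implemented as union-find over a position-sorted sliding window,
  which is exact for this linkage relation; equality with a brute-force
  connected-components oracle is property-tested. Identical pairs
  (same coordinates and strands) are collapsed before support counting.
  `min_support` defaults to 6.
* **Breakpoint refinement.** Under the orientation convention every read
  points toward its junction; a read at leftmost position *p* pointing right
  bounds the last retained base to [*p* + rl − 1, *p* + cutoff] (mirrored
  leftward). Two defensive layers sit on top of the plain intersection of
  these bounds, both motivated by contamination:
  1. *Implied-insert trimming.* For an honest member, both read positions
     differ from the true junction pair by one fragment insert, so the
     position difference (or sum, when the two sides point the same way) is
     constant across the cluster up to insert variation. Members deviating
     from the cluster median by more than five insert MADs (cutoff/8 when
     the MAD is unknown) are excluded from the bound computation — they are
     either fragments from the far log-normal tail (insert > cutoff, which
     would invalidate the outer bound) or contaminant pairs that straddle
     the junction and mimic the cluster's signature with inverted geometry.
     They still count toward support.
  2. *Deepest-coverage consensus.* The interval reported is the region
     covered by the largest number of per-member bounds (ties resolved
     toward the median of bound midpoints, then leftmost). For a clean
     cluster this equals the intersection, whose width is at most the cutoff
     and non-increasing as members accumulate.

  The interval convention brackets the **last retained base** on each side,
  matching how validated junctions are reported (the retained base at the
  breakpoint position); consequently a read ending exactly on the breakpoint
  base still leaves the truth inside the interval.
* **Typing.** Long-span clusters with the concordant strand signature are
  deletions. Same-strand clusters are inversion junctions; a (−,−)/(+,+)
  pair on one chromosome whose intervals agree within the cutoff merges into
  one inversion call (greedy, smallest combined midpoint distance), classed
  pericentric iff the centromere interval lies between the breakpoint
  midpoints. Inter-chromosomal clusters with complementary strand
  signatures merge the same way into reciprocal translocations; unpaired
  clusters remain lone junctions. Everted-orientation clusters — opposite
  strands in the reversed order — are the signature of short-insert
  paired-end contamination under a mate-pair convention (or of tandem
  duplication, which this caller does not call) and are discarded with a
  curation-log reason rather than typed; without this rule, chains of
  contaminant pairs exceed the six-pair threshold at realistic contamination
  rates and specificity collapses. Span is |bp₂ − bp₁| over breakpoint
  midpoints; externally validated base-pair positions can replace interval
  midpoints via `with_validated_breakpoints`, which recomputes span and
  centromere class.
* **Curation log.** Every discarded cluster or pair group becomes one
  structured JSON entry (reason + context). This is the package's
  machine-readable replacement for interactive manual curation.
* **Junction reconciliation.** `junction_delta(ref_left, ref_right,
  junction)` assumes the flanks end/begin exactly at the two breakpoints and
  share their outer ends with the sequenced junction; after maximal prefix/
  suffix anchoring (≥ 10 bp each, ≤ 10 unexplained bases) the net indel is
  len(junction) − len(flanks): negative bases were lost, positive
  duplicated. Validated against junctions cut from simulator-derived
  sequences with planted ±1 bp indels.

## Annotation

Gene models are single-transcript (the longest transcript stands for the
gene, one `RefSeq`-style row per gene); exons and introns are numbered in
transcript order, so intron *k* separates exons *k* and *k*+1 on either
strand. When several genes overlap a breakpoint all are reported and the
longest is primary. Fusion prediction works on the call's derived-genome
adjacencies (which flank of each breakpoint the derivative retains): a
fusion is emitted only when the two genes' derived-strand directions agree,
the 5′ gene contributing its transcript prefix and the 3′ gene its suffix;
reading-frame preservation is not assessed and is reported as unknown.
Cytobands use the UCSC file convention, converted to 1-based closed with
boundary ties going to the earlier band; karyotype tokens degrade to
coordinate form (with a warning) when a band lookup fails.

## Metrics

Spanning depth is the plain formula n_pairs × median_insert / genome_size
with no hidden filtering; note that published spanning-depth figures for
real libraries sometimes reflect additional, unstated read filtering, so the
plain formula can legitimately disagree with a quoted number for the same
library. Enrichment reports both the length-normalized fold
(observed fraction / length-proportional fraction) and the raw observed
fraction, since either convention appears in practice. Validation matches
calls of the same type family at ≥ 0.5 reciprocal overlap (both breakpoints
within 10 kb for translocations); the rate is rounded to integer percent for
display with the exact fraction retained.

## Problem sizes and defaults

The recovery experiments use a 2-chromosome, 20 Mb genome carrying one
reciprocal translocation, one pericentric and one paracentric inversion and
one 15 kb deletion, with 100,000 pairs at median insert 5,000 bp (sd 750),
36 bp reads and 2 % contamination — a spanning depth of 25×, comfortably
above the six-pair threshold at every junction while keeping a full
simulate-call cycle under two seconds. Specificity runs use the same genome
with no planted events, 50,000 pairs and 5 % contamination over twenty
seeds. Insert sd and contamination rate are simulator knobs chosen as
realistic for enriched 5 kb libraries (~15 % CV; low single-digit percent
contamination), not claims about any particular dataset.

## Known limitations

Tandem duplications, insertions and CNV-from-depth are out of scope; the
caller reports everted clusters to the log instead. Breakpoints in repeats
are only as good as the alignments fed in — the simulator does not model
mis-mapping. Fusion prediction is exon-granular and single-transcript;
isoform-specific consequences are not enumerated. The span point estimate
uses interval midpoints and is accordingly fuzzy at cluster resolution
(hundreds of bp to a few kb) until validated breakpoints are supplied.
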