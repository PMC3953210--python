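"""Gene-level and cytogenetic annotation of SV calls.

Three layers:

* ``locate_breakpoint`` — which gene (if any) a breakpoint falls in and
  where (exon k / intron k in transcript order, or intergenic with distance
  and an upstream/downstream label relative to the nearest gene).
* ``predict_fusions`` — given a call's derived-genome adjacencies, decide
  whether transcription can run through each junction.  A fusion transcript
  is predicted only when one gene's 5' portion is joined to another gene's
  3' portion with a consistent direction of transcription across the
  junction; genes that end up transcribing toward (or away from) each other
  yield no fusion.  A reciprocal translocation can produce up to two fusion
  products, one per derivative.
* ``band_for_position`` / ``karyotype_string`` — cytoband lookup and
  ISCN-style tokens (t(2;7)(p25.1;q33), inv(2)(q32.1q32.1), del(19)(q13.4))
  assembled into a revised karyotype string.

Fusion prediction works at exon granularity; reading-frame preservation is
not assessed and is reported as unknown.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

from intervaltree import IntervalTree

from matesv.calling import SVCall, Adjacency, chrom_sort_key


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A stranded single-transcript gene model.

    ``exons`` are (start, end) intervals, 1-based inclusive, in genomic
    order.  Exon numbering used everywhere is *transcript* order (5'->3'),
    so on the minus strand exon 1 is the genomically last exon.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple
    biotype: str = "protein_coding"

    def __post_init__(self):
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if exons and not (self.start <= exons[0][0] and exons[-1][1] <= self.end):
            raise ValueError(f"{self.gene_id}: transcript interval does not cover exons")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def exon_number(self, genomic_index: int) -> int:
        """Transcript-order number of the exon at 0-based genomic index."""
        if self.strand == "+":
            return genomic_index + 1
        return self.n_exons - genomic_index


class GeneIndex:
    """Interval-indexed gene set for fast breakpoint queries."""

    def __init__(self, genes: Iterable):
        self.genes = list(genes)
        self._trees: dict = {}
        self._by_chrom: dict = {}
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: g.start)

    def overlapping(self, chrom: str, pos: int) -> list:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.at(pos)]
        hits.sort(key=lambda g: (-g.length, g.gene_id))  # primary = longest transcript
        return hits

    def nearest(self, chrom: str, pos: int):
        """(gene, distance) of the nearest gene on the chromosome, or None."""
        lst = self._by_chrom.get(chrom)
        if not lst:
            return None
        best, best_d = None, None
        for g in lst:  # gene sets here are small; linear scan is fine
            if g.start <= pos <= g.end:
                d = 0
            else:
                d = min(abs(pos - g.start), abs(pos - g.end))
            if best_d is None or d < best_d:
                best, best_d = g, d
        return best, best_d


@dataclass
class BreakpointAnnotation:
    chrom: str
    pos: int
    gene: Optional[GeneModel]            # primary (longest) overlapping gene
    region: str                          # 'exon3' | 'intron1' | 'intergenic'
    region_kind: str                     # 'exon' | 'intron' | 'upstream' | 'downstream'
    region_number: Optional[int] = None  # transcript-order exon/intron number
    overlapping_genes: list = field(default_factory=list)
    nearest_gene: Optional[GeneModel] = None
    distance: Optional[int] = None       # to nearest gene if intergenic

    @property
    def intergenic(self) -> bool:
        return self.gene is None


def locate_breakpoint(bp: tuple, genes: GeneIndex) -> BreakpointAnnotation:
    """Annotate a (chrom, pos) breakpoint against the gene set.

    All overlapping genes are reported; the primary gene is the one with the
    longest transcript.  Exons and introns are numbered in transcript order,
    so intron k separates exon k from exon k+1 regardless of strand.
    """
    chrom, pos = bp
    hits = genes.overlapping(chrom, pos)
    if not hits:
        near = genes.nearest(chrom, pos)
        if near is None:
            return BreakpointAnnotation(chrom, pos, None, "intergenic", "upstream")
        gene, dist = near
        before = pos < gene.start
        kind = ("upstream" if (before == (gene.strand == "+")) else "downstream")
        return BreakpointAnnotation(chrom, pos, None, "intergenic", kind,
                                    nearest_gene=gene, distance=dist)
    g = hits[0]
    region_kind, number = _region_within(g, pos)
    return BreakpointAnnotation(chrom, pos, g, f"{region_kind}{number}",
                                region_kind, number, overlapping_genes=hits)


def _region_within(g: GeneModel, pos: int) -> tuple:
    for gi, (s, e) in enumerate(g.exons):
        if s <= pos <= e:
            return "exon", g.exon_number(gi)
    for gi, ((_, e1), (s2, _)) in enumerate(zip(g.exons, g.exons[1:])):
        if e1 < pos < s2:
            # intron k sits between exons k and k+1 in transcript order
            if g.strand == "+":
                return "intron", gi + 1
            return "intron", g.n_exons - gi - 1
    # inside the transcript interval but outside any exon/intron span
    # (UTR padding): label relative to transcript ends
    if (pos < g.exons[0][0]) == (g.strand == "+"):
        return "upstream", 0
    return "downstream", 0


# ---------------------------------------------------------------------------
# fusion prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionPrediction:
    """A predicted fusion transcript across one derived junction."""

    five_prime_gene: str
    five_prime_exons: tuple    # (first, last) retained, transcript order
    three_prime_gene: str
    three_prime_exons: tuple
    label: str
    orientation_compatible: bool = True
    frame: str = "unknown"


def _exon_range_label(rng: tuple) -> str:
    a, b = rng
    return f"ex{a}" if a == b else f"ex{a}-{b}"


def _retained_prefix(g: GeneModel, region_kind: str, number: int) -> Optional[tuple]:
    """Transcript-order exons retained by the 5' (donor) gene."""
    if region_kind == "intron":
        return (1, number)
    if region_kind == "exon":  # exon itself truncated: complete exons end at k-1
        return (1, number) if number >= 1 else None
    return None


def _retained_suffix(g: GeneModel, region_kind: str, number: int) -> Optional[tuple]:
    """Transcript-order exons retained by the 3' (acceptor) gene."""
    if region_kind == "intron":
        return (number + 1, g.n_exons)
    if region_kind == "exon":
        return (number, g.n_exons)
    return None


def predict_fusions(call: SVCall, genes: GeneIndex) -> list:
    """Predict fusion transcripts for every junction of a call.

    For each adjacency the derived-strand direction of the gene on each side
    is computed (a gene inside an inverted piece flips).  Transcription runs
    through the junction only when both derived directions agree; the gene
    transcribing *into* the junction donates its 5' exons and the gene
    transcribing *out of* it contributes its 3' exons.  Orientation-
    incompatible junctions yield nothing.
    """
    if not call.adjacencies:
        raise ValueError("call carries no junction adjacencies")
    fusions = []
    for adj in call.adjacencies:
        ann1 = locate_breakpoint((adj.chrom1, adj.pos1), genes)
        ann2 = locate_breakpoint((adj.chrom2, adj.pos2), genes)
        if ann1.gene is None or ann2.gene is None:
            continue
        g1, g2 = ann1.gene, ann2.gene
        if g1.gene_id == g2.gene_id:
            continue  # junction internal to one gene: disruption, not fusion
        orient1 = "+" if adj.keep1 == "left" else "-"   # side-1 piece on derived strand
        orient2 = "+" if adj.keep2 == "right" else "-"  # side-2 piece on derived strand
        der1 = g1.strand if orient1 == "+" else _flip_strand(g1.strand)
        der2 = g2.strand if orient2 == "+" else _flip_strand(g2.strand)
        if der1 != der2:
            continue  # genes transcribe toward/away from each other: no fusion
        if der1 == "+":
            donor, don_ann, acceptor, acc_ann = g1, ann1, g2, ann2
        else:
            donor, don_ann, acceptor, acc_ann = g2, ann2, g1, ann1
        pre = _retained_prefix(donor, don_ann.region_kind, don_ann.region_number or 0)
        suf = _retained_suffix(acceptor, acc_ann.region_kind, acc_ann.region_number or 0)
        if pre is None or suf is None or pre[1] < pre[0] or suf[0] > suf[1]:
            continue
        label = (f"{donor.gene_name}{_exon_range_label(pre)}"
                 f"_{acceptor.gene_name}{_exon_range_label(suf)}")
        fusions.append(FusionPrediction(
            five_prime_gene=donor.gene_name, five_prime_exons=pre,
            three_prime_gene=acceptor.gene_name, three_prime_exons=suf,
            label=label))
    return fusions


def _flip_strand(s: str) -> str:
    return "-" if s == "+" else "+"


# ---------------------------------------------------------------------------
# cytobands and karyotype strings
# ---------------------------------------------------------------------------

def load_cytobands(path) -> dict:
    """Read a UCSC cytoBand.txt table (chrom, start, end, band, stain).

    The file is 0-based half-open; internally bands become 1-based closed,
    so a position exactly on a shared boundary belongs to the earlier band.
    """
    bands: dict = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{line_no}: expected >= 4 tab-separated columns")
            chrom, start, end, band = parts[0], int(parts[1]), int(parts[2]), parts[3]
            bands.setdefault(chrom, []).append((start + 1, end, band))
    for chrom in bands:
        bands[chrom].sort()
    return bands


def band_for_position(cytobands: dict, chrom: str, pos: int) -> str:
    """The unique band containing ``pos`` (bands partition each chromosome)."""
    if chrom not in cytobands:
        raise KeyError(f"no cytobands for chromosome {chrom!r}")
    rows = cytobands[chrom]
    i = bisect.bisect_right([r[0] for r in rows], pos) - 1
    if i < 0 or not (rows[i][0] <= pos <= rows[i][1]):
        raise KeyError(f"position {chrom}:{pos} outside the band map")
    return rows[i][2]


@dataclass
class KaryotypeReport:
    tokens: list
    karyotype: str


def _chrom_label(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def karyotype_string(calls: list, cytobands: dict,
                     base_karyotype: str = "46,XY") -> KaryotypeReport:
    """ISCN-like tokens for each call, joined onto a base karyotype.

    Reciprocal translocations and lone junctions become t(a;b)(bandA;bandB);
    inversions inv(c)(band1band2); deletions del(c)(band) (two bands when the
    breakpoints fall in different bands).  A failed band lookup degrades that
    token to coordinate form with a warning.
    """
    entries = []
    for call in calls:
        (ivA, ivB) = call.intervals[0]
        bpA, bpB = ivA.midpoint, ivB.midpoint
        try:
            bandA = band_for_position(cytobands, ivA.chrom, bpA)
            bandB = band_for_position(cytobands, ivB.chrom, bpB)
        except KeyError as exc:
            warnings.warn(f"band lookup failed ({exc}); emitting coordinate token")
            bandA = bandB = None
        cA, cB = _chrom_label(ivA.chrom), _chrom_label(ivB.chrom)
        if call.sv_type in ("reciprocal_translocation", "translocation_junction"):
            token = (f"t({cA};{cB})({bandA};{bandB})" if bandA else
                     f"t({cA};{cB})({ivA.chrom}:{bpA};{ivB.chrom}:{bpB})")
        elif call.sv_type == "inversion":
            token = (f"inv({cA})({bandA}{bandB})" if bandA else
                     f"inv({cA})({ivA.chrom}:{bpA}-{bpB})")
        else:  # deletion
            if bandA is None:
                token = f"del({cA})({ivA.chrom}:{bpA}-{bpB})"
            elif bandA == bandB:
                token = f"del({cA})({bandA})"
            else:
                token = f"del({cA})({bandA}{bandB})"
        entries.append(((chrom_sort_key(ivA.chrom), bpA), token))
    entries.sort(key=lambda t: t[0])
    tokens = [t for _, t in entries]
    karyotype = base_karyotype if not tokens else base_karyotype + "," + ",".join(tokens)
    return KaryotypeReport(tokens=tokens, karyotype=karyotype)


# ---------------------------------------------------------------------------
# Table-style disrupted-gene report
# ---------------------------------------------------------------------------

def disrupted_gene_report(calls: list, genes: GeneIndex, cytobands: Optional[dict] = None):
    """One row per (call, breakpoint, disrupted gene): the per-SV gene table.

    Returns a list of dicts with the karyotype token, breakpoint, disrupted
    gene, transcript position, exon count and any predicted fusion label.
    """
    rows = []
    for i, call in enumerate(calls, 1):
        fusions = []
        try:
            fusions = predict_fusions(call, genes)
        except ValueError:
            pass
        token = None
        if cytobands is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                token = karyotype_string([call], cytobands).tokens[0]
        for (chromA, bpA), (chromB, bpB) in call.breakpoints():
            for chrom, bp in ((chromA, bpA), (chromB, bpB)):
                ann = locate_breakpoint((chrom, bp), genes)
                if ann.gene is None:
                    continue
                rows.append({
                    "sv_no": i,
                    "sv_type": call.sv_type,
                    "karyotype_token": token,
                    "breakpoint": f"{chrom}:{bp}",
                    "gene": ann.gene.gene_name,
                    "transcript_position": f"{ann.gene.chrom}:{ann.gene.start}-{ann.gene.end}",
                    "region": ann.region,
                    "exon_count": ann.gene.n_exons,
                    "fusion": ";".join(f.label for f in fusions) or "none",
                    "support": call.support,
                })
    return rows
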