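"""Discordant-read-pair structural-variant calling.

The discovery procedure, stage by stage:

1. ``estimate_insert_stats`` — median insert size of concordantly oriented
   same-chromosome pairs; the discordance distance cutoff is fixed at twice
   that median (for a 5 kb mate-pair library, ~10 kb).
2. ``classify_pair`` — every pair is assigned exactly one class with fixed
   precedence: duplicate > low_quality > interchromosomal > long_span >
   orientation_aberrant > concordant.
3. ``cluster_discordant`` — single-linkage clustering of discordant pairs
   that share a signature (chromosome pair + strand pair); two pairs link
   when both of their end positions lie within the cutoff.  Clusters with
   fewer than six supporting pairs (after duplicate removal) are discarded.
4. ``refine_intervals`` — each cluster side gets a breakpoint interval
   bounded by the innermost supporting read base and the outermost position
   still compatible with the insert-size cutoff; intersecting the per-member
   bounds narrows the interval as support grows.
5. ``type_svs`` — clusters become typed calls: long-span/concordant-strand
   clusters are deletions; same-strand clusters are inversion junctions
   (paired into a single inversion call, peri- or paracentric depending on
   the centromere); interchromosomal clusters with complementary strand
   signatures merge into reciprocal translocations.  Everted-orientation
   clusters (the signature of short-insert paired-end contamination in a
   mate-pair library) are discarded with a machine-readable reason.
6. ``junction_delta`` — reconciles a sequenced junction against the two
   reference flanks, reporting bases lost or duplicated at the breakpoint.

Breakpoint convention: an interval bounds the position of the last retained
base on the cluster's pointing side, matching how validated junctions are
conventionally reported.  Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import enum
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Optional

import numpy as np


class ReadEnd(NamedTuple):
    chrom: str
    pos: int          # 1-based leftmost aligned base
    strand: str       # '+' or '-'
    mapq: int


@dataclass(frozen=True, slots=True)
class ReadPairRecord:
    """One aligned mate pair — the caller's atomic input."""

    pair_id: str
    endA: ReadEnd
    endB: ReadEnd
    duplicate_flag: bool = False
    source_tag: str = ""


class DiscordantClass(enum.Enum):
    CONCORDANT = "concordant"
    INTERCHROMOSOMAL = "interchromosomal"
    LONG_SPAN = "long_span"
    ORIENTATION_ABERRANT = "orientation_aberrant"
    LOW_QUALITY = "low_quality"
    DUPLICATE = "duplicate"


DISCORDANT_CLASSES = frozenset(
    {DiscordantClass.INTERCHROMOSOMAL, DiscordantClass.LONG_SPAN,
     DiscordantClass.ORIENTATION_ABERRANT}
)


@dataclass(frozen=True)
class CallerConfig:
    """Tunable thresholds of the discovery procedure.

    ``orientation`` is the concordant convention as (left-read, right-read)
    strands: 'RF' (outward-facing, the mate-pair default after
    circularization) or 'FR' (standard paired-end).  ``read_length`` is used
    to convert leftmost alignment positions into outer insert spans and into
    innermost breakpoint bounds.
    """

    orientation: str = "RF"
    read_length: int = 36
    mapq_threshold: int = 20
    min_support: int = 6
    nominal_insert: int = 5000
    median_override: Optional[int] = None
    min_insert_pairs: int = 100

    def __post_init__(self):
        if self.orientation not in ("RF", "FR"):
            raise ValueError("orientation must be 'RF' or 'FR'")
        for name in ("read_length", "mapq_threshold", "min_support", "nominal_insert"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def concordant_strands(self) -> tuple:
        return ("-", "+") if self.orientation == "RF" else ("+", "-")

    def points_right(self, strand: str) -> bool:
        """Does a read on this strand point toward larger coordinates?

        Under the RF convention the genomically left read of a fragment is
        reverse, so a reverse read has its junction/mate to the right.
        """
        return strand == self.concordant_strands[0]


@dataclass(frozen=True)
class InsertStats:
    """Library insert statistics and the derived discordance cutoff."""

    median_insert: int
    mad: int
    n_used: int
    cutoff: int  # distance threshold = 2 x median insert

    @classmethod
    def from_median(cls, median_insert: int, mad: int = 0, n_used: int = 0):
        return cls(median_insert=int(median_insert), mad=int(mad),
                   n_used=n_used, cutoff=2 * int(median_insert))


class BreakpointInterval(NamedTuple):
    chrom: str
    start: int
    end: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


class ClusterSignature(NamedTuple):
    chromA: str
    strandA: str
    chromB: str
    strandB: str


@dataclass
class DiscordantCluster:
    """Same-signature discordant pairs supporting one junction."""

    signature: ClusterSignature
    members: list
    support: int
    intervalA: Optional[BreakpointInterval] = None
    intervalB: Optional[BreakpointInterval] = None

    @property
    def interchromosomal(self) -> bool:
        return self.signature.chromA != self.signature.chromB


@dataclass
class SVCall:
    """A typed rearrangement call.

    ``intervals`` holds one breakpoint-interval pair per junction: one pair
    for deletions, inversions and lone translocation junctions; two for a
    reciprocal translocation.  ``adjacencies`` encodes, per junction, which
    flank of each breakpoint is retained in the derivative ('left' or
    'right'), which is what fusion prediction needs.
    """

    sv_type: str  # deletion | inversion | translocation_junction | reciprocal_translocation
    intervals: list
    support: int
    span: Optional[int] = None
    inversion_class: str = "NA"  # pericentric | paracentric | NA
    adjacencies: list = field(default_factory=list)
    clusters: list = field(default_factory=list, repr=False)

    @property
    def chromA(self) -> str:
        return self.intervals[0][0].chrom

    @property
    def chromB(self) -> str:
        return self.intervals[0][1].chrom

    def breakpoints(self) -> list:
        """Midpoint estimates, one (chrom, pos) pair per junction."""
        return [((a.chrom, a.midpoint), (b.chrom, b.midpoint)) for a, b in self.intervals]


class Adjacency(NamedTuple):
    """One derived-genome junction: (chrom, pos, retained flank) x 2.

    Side 1 is the derived-left piece, side 2 the derived-right piece.  A side
    that keeps its 'left' flank enters the junction in reference-forward
    orientation when on side 1 (and inverted on side 2), and vice versa.
    """

    chrom1: str
    pos1: int
    keep1: str  # 'left' | 'right'
    chrom2: str
    pos2: int
    keep2: str


class CurationLog:
    """Machine-readable record of everything the caller discarded and why.

    Replaces interactive manual curation: every dropped cluster or pair group
    is one structured entry.
    """

    def __init__(self):
        self.entries = []

    def add(self, reason: str, **details):
        self.entries.append({"reason": reason, **details})

    def to_json(self) -> str:
        return json.dumps(self.entries, indent=2)

    def __len__(self):
        return len(self.entries)


class InsufficientPairsError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_num_re = re.compile(r"(\d+)")


def chrom_sort_key(name: str):
    """Natural sort: chr2 < chr7 < chr10; non-numeric parts lexicographic."""
    return tuple(int(p) if p.isdigit() else p for p in _num_re.split(name))


def canonical_ends(pair: ReadPairRecord) -> tuple:
    """(endA, endB) reordered so endA <= endB by (chromosome, position)."""
    a, b = pair.endA, pair.endB
    if (chrom_sort_key(a.chrom), a.pos) <= (chrom_sort_key(b.chrom), b.pos):
        return a, b
    return b, a


def pair_span(pair: ReadPairRecord, read_length: int) -> int:
    """Outer insert span of a same-chromosome pair (leftmost to rightmost base)."""
    a, b = canonical_ends(pair)
    return (b.pos - a.pos) + read_length


# ---------------------------------------------------------------------------
# stage 1: insert statistics
# ---------------------------------------------------------------------------

def estimate_insert_stats(pairs: Iterable, config: CallerConfig = CallerConfig()) -> InsertStats:
    """Median insert of concordantly oriented same-chromosome pairs.

    Pairs with spans beyond 10x the nominal insert are excluded from the
    estimate (they are discordant candidates, not library behaviour).  The
    discordance cutoff is fixed at twice the median.  If fewer than
    ``config.min_insert_pairs`` usable pairs exist, ``config.median_override``
    must be set, otherwise a hard error names the shortfall.
    """
    conv = config.concordant_strands
    limit = 10 * config.nominal_insert
    spans = []
    for p in pairs:
        if p.duplicate_flag:
            continue
        a, b = canonical_ends(p)
        if a.chrom != b.chrom or (a.strand, b.strand) != conv:
            continue
        span = (b.pos - a.pos) + config.read_length
        if 0 < span < limit:
            spans.append(span)
    if len(spans) < config.min_insert_pairs:
        if config.median_override is not None:
            return InsertStats.from_median(config.median_override, n_used=len(spans))
        raise InsufficientPairsError(
            f"only {len(spans)} usable concordant pairs for insert estimation "
            f"(need >= {config.min_insert_pairs}); set median_override"
        )
    arr = np.asarray(spans)
    med = int(np.median(arr))
    mad = int(np.median(np.abs(arr - med)))
    return InsertStats(median_insert=med, mad=mad, n_used=len(arr), cutoff=2 * med)


# ---------------------------------------------------------------------------
# stage 2: classification
# ---------------------------------------------------------------------------

def classify_pair(pair: ReadPairRecord, stats: InsertStats,
                  config: CallerConfig = CallerConfig()) -> DiscordantClass:
    """Assign one mutually exclusive class to a pair (fixed precedence)."""
    if pair.duplicate_flag:
        return DiscordantClass.DUPLICATE
    if min(pair.endA.mapq, pair.endB.mapq) < config.mapq_threshold:
        return DiscordantClass.LOW_QUALITY
    a, b = canonical_ends(pair)
    if a.chrom != b.chrom:
        return DiscordantClass.INTERCHROMOSOMAL
    if (b.pos - a.pos) + config.read_length > stats.cutoff:
        return DiscordantClass.LONG_SPAN
    if (a.strand, b.strand) != config.concordant_strands:
        return DiscordantClass.ORIENTATION_ABERRANT
    return DiscordantClass.CONCORDANT


# ---------------------------------------------------------------------------
# stage 3: clustering
# ---------------------------------------------------------------------------

class _DSU:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_discordant(pairs: Iterable, stats: InsertStats, min_support: int = 6,
                       config: CallerConfig = CallerConfig(),
                       log: Optional[CurationLog] = None) -> list:
    """Single-linkage clustering of discordant pairs within each signature.

    Two pairs link iff both endA positions and both endB positions (after
    canonical end ordering) lie within ``stats.cutoff``.  Duplicate pairs
    (identical end coordinates and strands) are removed before support is
    counted.  Clusters below ``min_support`` are discarded (and logged).
    Output is sorted by (chromA, leftmost endA position).
    """
    cutoff = stats.cutoff
    by_sig: dict = {}
    seen = set()
    n_dup = 0
    for p in pairs:
        a, b = canonical_ends(p)
        key = (a.chrom, a.pos, a.strand, b.chrom, b.pos, b.strand)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        sig = ClusterSignature(a.chrom, a.strand, b.chrom, b.strand)
        by_sig.setdefault(sig, []).append((a.pos, b.pos, p))
    if log is not None and n_dup:
        log.add("duplicate_pairs_removed", count=n_dup)

    clusters = []
    for sig, rows in by_sig.items():
        rows.sort(key=lambda r: (r[0], r[1]))
        n = len(rows)
        dsu = _DSU(n)
        for i in range(n):
            pa_i, pb_i, _ = rows[i]
            j = i + 1
            while j < n and rows[j][0] - pa_i <= cutoff:
                if abs(rows[j][1] - pb_i) <= cutoff:
                    dsu.union(i, j)
                j += 1
        groups: dict = {}
        for i in range(n):
            groups.setdefault(dsu.find(i), []).append(rows[i])
        for rows_g in groups.values():
            members = [r[2] for r in rows_g]
            if len(members) < min_support:
                if log is not None:
                    log.add("below_min_support", signature=tuple(sig),
                            support=len(members), min_support=min_support,
                            posA=min(r[0] for r in rows_g),
                            posB=min(r[1] for r in rows_g))
                continue
            clusters.append(DiscordantCluster(signature=sig, members=members,
                                              support=len(members)))
    clusters.sort(key=lambda c: (chrom_sort_key(c.signature.chromA),
                                 min(canonical_ends(m)[0].pos for m in c.members)))
    return clusters


# ---------------------------------------------------------------------------
# stage 4: breakpoint-interval refinement
# ---------------------------------------------------------------------------

def _side_interval(chrom: str, positions: list, strand: str, stats: InsertStats,
                   config: CallerConfig) -> BreakpointInterval:
    """Consensus of per-read breakpoint bounds on one cluster side.

    A read pointing right (toward its junction) at leftmost position p allows
    the last retained base to lie in [p + read_length - 1, p + cutoff]:
    no earlier than its own innermost aligned base, no farther than the
    insert-size cutoff from its outer edge.  Mirrored for left-pointing
    reads.

    The interval returned is the deepest-coverage region of the per-member
    bounds — the intersection of the largest mutually consistent subset.
    For a clean cluster this is the plain intersection, which only narrows as
    members accumulate; members whose bounds contradict the majority (e.g.
    short-insert contaminant pairs that happen to straddle the junction and
    so violate the mate-pair geometry) are outvoted instead of corrupting
    the interval.
    """
    rl = config.read_length
    cutoff = stats.cutoff
    positions = [int(p) for p in positions]
    if config.points_right(strand):
        bounds = [(p + rl - 1, p + cutoff) for p in positions]
    else:
        bounds = [(p + rl - 1 - cutoff, p) for p in positions]
    events = []
    for lo, hi in bounds:
        events.append((lo, 1))
        events.append((hi + 1, -1))
    events.sort()
    # sweep for the maximum-depth segments
    segments = []  # (depth, start, end)
    depth, i, n = 0, 0, len(events)
    while i < n:
        x = events[i][0]
        while i < n and events[i][0] == x:
            depth += events[i][1]
            i += 1
        if i < n and depth > 0:
            segments.append((depth, x, events[i][0] - 1))
    max_depth = max(d for d, _, _ in segments)
    med = float(np.median([(lo + hi) / 2 for lo, hi in bounds]))
    lo, hi = min(
        ((s, e) for d, s, e in segments if d == max_depth),
        key=lambda se: (abs((se[0] + se[1]) / 2 - med), se[0]),
    )
    return BreakpointInterval(chrom, max(lo, 1), max(hi, 1))


def refine_intervals(cluster: DiscordantCluster, stats: InsertStats,
                     config: CallerConfig = CallerConfig()) -> DiscordantCluster:
    """Attach refined breakpoint intervals to a cluster (returns a copy).

    Before the geometric bounds are intersected, members whose *implied
    insert size* is inconsistent with the cluster are set aside.  Both read
    positions of an honest member differ from the junction coordinates by one
    fragment insert, so (up to a constant shared by the whole cluster) the
    position difference — or the position sum, when both sides point the
    same way — measures that member's insert.  Members deviating from the
    cluster median by more than one median insert (half the cutoff) are
    either fragments from the far tail of the insert distribution or
    short-insert contaminant pairs that happen to straddle the junction;
    both violate the bound geometry and would corrupt the interval.  They
    still count toward support.  The deviation tolerance is five insert
    MADs (an eighth of the cutoff when the library MAD is unknown): wide
    against honest insert dispersion, far below the ~one-median-insert
    deviation a junction-straddling contaminant shows.
    """
    if not cluster.members:
        raise ValueError("cannot refine an empty cluster")
    endsA, endsB = [], []
    for m in cluster.members:
        a, b = canonical_ends(m)
        if (a.strand, b.strand) != (cluster.signature.strandA, cluster.signature.strandB):
            raise ValueError("cluster members disagree in strand signature")
        endsA.append(a.pos)
        endsB.append(b.pos)
    endsA = np.asarray(endsA)
    endsB = np.asarray(endsB)
    same_direction = (config.points_right(cluster.signature.strandA)
                      == config.points_right(cluster.signature.strandB))
    implied = endsB + endsA if same_direction else endsB - endsA
    tolerance = max(5 * stats.mad, stats.cutoff / 8)
    keep = np.abs(implied - np.median(implied)) <= tolerance
    if not keep.any():
        keep[:] = True
    intervalA = _side_interval(cluster.signature.chromA, endsA[keep],
                               cluster.signature.strandA, stats, config)
    intervalB = _side_interval(cluster.signature.chromB, endsB[keep],
                               cluster.signature.strandB, stats, config)
    return replace(cluster, intervalA=intervalA, intervalB=intervalB)


# ---------------------------------------------------------------------------
# stage 5: SV typing
# ---------------------------------------------------------------------------

def _keep_side(strand: str, config: CallerConfig) -> str:
    """Which flank of the breakpoint the supporting reads sit on (and retain)."""
    return "left" if config.points_right(strand) else "right"


def _intersect(i1: BreakpointInterval, i2: BreakpointInterval) -> BreakpointInterval:
    lo, hi = max(i1.start, i2.start), min(i1.end, i2.end)
    if lo > hi:  # disjoint estimates: fall back to the hull
        lo, hi = min(i1.start, i2.start), max(i1.end, i2.end)
    return BreakpointInterval(i1.chrom, lo, hi)


def _pericentric(bp1: int, bp2: int, centromere) -> str:
    if centromere is None:
        return "NA"
    lo, hi = sorted((bp1, bp2))
    return "pericentric" if lo <= centromere[0] and centromere[1] <= hi else "paracentric"


def _greedy_pairing(left: list, right: list, cutoff: int):
    """Match clusters across two lists by smallest combined interval distance."""
    candidates = []
    for i, c1 in enumerate(left):
        for j, c2 in enumerate(right):
            dA = abs(c1.intervalA.midpoint - c2.intervalA.midpoint)
            dB = abs(c1.intervalB.midpoint - c2.intervalB.midpoint)
            if dA <= cutoff and dB <= cutoff:
                candidates.append((dA + dB, i, j))
    candidates.sort()
    used_i, used_j, matches = set(), set(), []
    for _, i, j in candidates:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            matches.append((i, j))
    return matches


def type_svs(clusters: list, centromeres: Optional[dict], stats: InsertStats,
             config: CallerConfig = CallerConfig(),
             log: Optional[CurationLog] = None) -> list:
    """Turn refined discordant clusters into typed SV calls.

    See the module docstring for the typing rules.  ``centromeres`` maps
    chromosome name to a (start, end) interval; when absent, inversions are
    emitted with ``inversion_class='NA'`` and a warning.
    """
    conv = config.concordant_strands
    everted = (conv[1], conv[0])
    calls = []

    intra = [c for c in clusters if not c.interchromosomal]
    inter = [c for c in clusters if c.interchromosomal]
    for c in clusters:
        if c.intervalA is None or c.intervalB is None:
            raise ValueError("type_svs requires refined clusters")

    # --- intra-chromosomal -------------------------------------------------
    inv_minus: dict = {}
    inv_plus: dict = {}
    for c in intra:
        s = (c.signature.strandA, c.signature.strandB)
        if s == conv:
            span = abs(c.intervalB.midpoint - c.intervalA.midpoint)
            calls.append(SVCall(
                sv_type="deletion",
                intervals=[(c.intervalA, c.intervalB)],
                support=c.support, span=span,
                adjacencies=[Adjacency(c.intervalA.chrom, c.intervalA.midpoint, "left",
                                       c.intervalB.chrom, c.intervalB.midpoint, "right")],
                clusters=[c]))
        elif s == ("-", "-") or s == ("+", "+"):
            target = inv_minus if s == ("-", "-") else inv_plus
            target.setdefault(c.signature.chromA, []).append(c)
        elif s == everted:
            if log is not None:
                log.add("everted_orientation_cluster",
                        detail="short-insert paired-end contamination signature "
                               "(or tandem duplication, not called)",
                        chrom=c.signature.chromA, support=c.support,
                        intervalA=tuple(c.intervalA), intervalB=tuple(c.intervalB))
        else:  # unreachable given canonical ordering, kept for safety
            if log is not None:
                log.add("unrecognised_signature", signature=tuple(c.signature))

    def _inversion_call(cluster_pair):
        members = [c for c in cluster_pair if c is not None]
        if len(members) == 2:
            iA = _intersect(members[0].intervalA, members[1].intervalA)
            iB = _intersect(members[0].intervalB, members[1].intervalB)
        else:
            iA, iB = members[0].intervalA, members[0].intervalB
        support = sum(c.support for c in members)
        bp1, bp2 = iA.midpoint, iB.midpoint
        chrom = iA.chrom
        cen = (centromeres or {}).get(chrom)
        if cen is None:
            if centromeres is None:
                warnings.warn("no centromere map supplied; inversion_class set to NA")
            klass = "NA" if centromeres is None else _pericentric(bp1, bp2, None)
        else:
            klass = _pericentric(bp1, bp2, cen)
        # junction 1 joins the left flank of bp1 to the inverted left flank of
        # bp2; junction 2 joins the inverted right flank of bp1 to the right
        # flank of bp2
        adjacencies = [Adjacency(chrom, bp1, "left", chrom, bp2, "left"),
                       Adjacency(chrom, bp1, "right", chrom, bp2, "right")]
        return SVCall(sv_type="inversion", intervals=[(iA, iB)], support=support,
                      span=abs(bp2 - bp1), inversion_class=klass,
                      adjacencies=adjacencies, clusters=members)

    for chrom in sorted(set(inv_minus) | set(inv_plus), key=chrom_sort_key):
        minus = inv_minus.get(chrom, [])
        plus = inv_plus.get(chrom, [])
        matches = _greedy_pairing(minus, plus, stats.cutoff)
        mi = {i for i, _ in matches}
        mj = {j for _, j in matches}
        for i, j in matches:
            calls.append(_inversion_call((minus[i], plus[j])))
        for i, c in enumerate(minus):
            if i not in mi:
                calls.append(_inversion_call((c,)))
        for j, c in enumerate(plus):
            if j not in mj:
                calls.append(_inversion_call((c,)))

    # --- inter-chromosomal -------------------------------------------------
    def _junction_adjacency(c: DiscordantCluster) -> Adjacency:
        return Adjacency(c.intervalA.chrom, c.intervalA.midpoint,
                         _keep_side(c.signature.strandA, config),
                         c.intervalB.chrom, c.intervalB.midpoint,
                         _keep_side(c.signature.strandB, config))

    by_pair: dict = {}
    for c in inter:
        by_pair.setdefault((c.signature.chromA, c.signature.chromB), []).append(c)
    flip = {"+": "-", "-": "+"}
    for (ca, cb), group in sorted(by_pair.items(),
                                  key=lambda kv: (chrom_sort_key(kv[0][0]),
                                                  chrom_sort_key(kv[0][1]))):
        by_strands: dict = {}
        for c in group:
            by_strands.setdefault((c.signature.strandA, c.signature.strandB), []).append(c)
        consumed = set()
        for s, cl in sorted(by_strands.items()):
            comp = (flip[s[0]], flip[s[1]])
            if s >= comp or comp not in by_strands:
                continue
            matches = _greedy_pairing(cl, by_strands[comp], stats.cutoff)
            for i, j in matches:
                c1, c2 = cl[i], by_strands[comp][j]
                consumed.add(id(c1))
                consumed.add(id(c2))
                calls.append(SVCall(
                    sv_type="reciprocal_translocation",
                    intervals=[(c1.intervalA, c1.intervalB),
                               (c2.intervalA, c2.intervalB)],
                    support=c1.support + c2.support,
                    adjacencies=[_junction_adjacency(c1), _junction_adjacency(c2)],
                    clusters=[c1, c2]))
        for c in group:
            if id(c) not in consumed:
                calls.append(SVCall(
                    sv_type="translocation_junction",
                    intervals=[(c.intervalA, c.intervalB)],
                    support=c.support,
                    adjacencies=[_junction_adjacency(c)],
                    clusters=[c]))

    calls.sort(key=lambda v: (chrom_sort_key(v.chromA), v.intervals[0][0].start,
                              chrom_sort_key(v.chromB), v.intervals[0][1].start))
    return calls


def with_validated_breakpoints(call: SVCall, breakpoints: list,
                               centromeres: Optional[dict] = None) -> SVCall:
    """Replace interval estimates with base-pair-validated positions.

    ``breakpoints`` is one ((chrom, pos), (chrom, pos)) pair per junction,
    e.g. from capillary sequencing of the junction PCR product.  Span and
    peri-/paracentric classification are recomputed.
    """
    if len(breakpoints) != len(call.intervals):
        raise ValueError("need one validated breakpoint pair per junction")
    intervals = [(BreakpointInterval(c1, p1, p1), BreakpointInterval(c2, p2, p2))
                 for (c1, p1), (c2, p2) in breakpoints]
    span = call.span
    klass = call.inversion_class
    if call.sv_type in ("deletion", "inversion"):
        (a, b), = intervals
        span = abs(b.midpoint - a.midpoint)
        if call.sv_type == "inversion" and centromeres is not None:
            klass = _pericentric(a.midpoint, b.midpoint, centromeres.get(a.chrom))
    adjacencies = [adj._replace(pos1=iv[0].midpoint, pos2=iv[1].midpoint)
                   for adj, iv in zip(call.adjacencies, intervals)]
    return replace(call, intervals=intervals, span=span, inversion_class=klass,
                   adjacencies=adjacencies)


def clusters_from_breakpoints(sv_type: str, chromA: str, posA: int, chromB: str,
                              posB: int, support: int = 6) -> list:
    """Synthetic refined clusters pinning a known junction to the base pair.

    Used to push externally validated breakpoints (e.g. from capillary
    sequencing of a junction PCR product) through the ordinary ``type_svs``
    arithmetic: each cluster carries point breakpoint intervals and the
    strand signature the given SV type produces under the RF convention.
    """
    ivA = BreakpointInterval(chromA, posA, posA)
    ivB = BreakpointInterval(chromB, posB, posB)
    if sv_type == "deletion":
        sigs = [("-", "+")]
    elif sv_type == "inversion":
        sigs = [("-", "-"), ("+", "+")]
    elif sv_type == "reciprocal_translocation":
        sigs = [("-", "+"), ("+", "-")]
    elif sv_type == "translocation_junction":
        sigs = [("-", "+")]
    else:
        raise ValueError(f"unknown sv_type {sv_type!r}")
    return [
        DiscordantCluster(signature=ClusterSignature(chromA, sA, chromB, sB),
                          members=[], support=support, intervalA=ivA, intervalB=ivB)
        for sA, sB in sigs
    ]


# ---------------------------------------------------------------------------
# stage 6: junction sequence reconciliation
# ---------------------------------------------------------------------------

class JunctionMatchError(ValueError):
    pass


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def junction_delta(ref_left: str, ref_right: str, junction: str,
                   min_anchor: int = 10) -> tuple:
    """Bases lost (negative) or duplicated (positive) at a sequenced junction.

    ``ref_left`` must end at the last retained base of the left flank and
    ``ref_right`` begin at the first retained base of the right flank, both
    on the derived strand; a perfectly balanced junction is then exactly
    their concatenation.  The junction prefix is maximally extended into
    ``ref_left`` and its suffix into ``ref_right``; the signed difference
    between the junction length and the summed flank lengths is the net
    indel.  Returns ``(delta, description)``.
    """
    if min(len(ref_left), len(ref_right)) < 20:
        raise ValueError("flanks must be at least 20 bp")
    k = _common_prefix(junction, ref_left)
    s = _common_prefix(junction[::-1], ref_right[::-1])
    if k < min_anchor or s < min_anchor:
        raise JunctionMatchError("not a junction of these references")
    unexplained = len(junction) - k - s
    if unexplained > 10:
        raise JunctionMatchError(
            f"{unexplained} junction bases match neither flank")
    delta = len(junction) - (len(ref_left) + len(ref_right))
    if delta == 0:
        desc = "balanced"
    elif delta < 0:
        desc = f"{-delta} bp lost"
    else:
        desc = f"{delta} bp duplicated"
    return delta, desc


# ---------------------------------------------------------------------------
# pipeline convenience
# ---------------------------------------------------------------------------

def call_svs(pairs: list, centromeres: Optional[dict] = None,
             config: CallerConfig = CallerConfig(),
             stats: Optional[InsertStats] = None,
             log: Optional[CurationLog] = None) -> tuple:
    """Run the full discovery chain on raw pairs.

    Returns ``(calls, stats, log)``.  Insert statistics are estimated from
    the data unless supplied.
    """
    if log is None:
        log = CurationLog()
    if stats is None:
        stats = estimate_insert_stats(pairs, config)
    discordant = [p for p in pairs
                  if classify_pair(p, stats, config) in DISCORDANT_CLASSES]
    clusters = cluster_discordant(discordant, stats, config.min_support, config, log)
    refined = [refine_intervals(c, stats, config) for c in clusters]
    calls = type_svs(refined, centromeres, stats, config, log)
    return calls, stats, log
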