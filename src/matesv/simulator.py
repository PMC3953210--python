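"""Rearranged-genome and mate-pair-library simulator.

Builds derivative chromosomes from a toy reference by applying planted
structural variants (deletions, inversions, reciprocal translocations, each
optionally with a small indel at the junction), keeps an exact liftover map
from derived to reference coordinates, and draws mate-pair fragments from the
derived genome so that both read ends can be reported as *reference-space*
alignments — i.e. the simulator plays the role of the aligner.  The planted
events and the liftover map are the ground truth against which the caller is
tested.

Coordinates are 1-based inclusive throughout this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from matesv.calling import ReadEnd, ReadPairRecord

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

SV_TYPES = ("deletion", "inversion", "reciprocal_translocation")


class SVPlanError(ValueError):
    """Raised when a set of planted SVs cannot be applied."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReference:
    """A small multi-chromosome reference genome.

    Parameters
    ----------
    chrom_names:
        Chromosome identifiers, in karyotype order.
    chrom_lengths:
        Length in bp of each chromosome, parallel to ``chrom_names``.
    centromeres:
        Per-chromosome centromere interval ``(start, end)``, 1-based
        inclusive.  Used to classify inversions as peri- vs paracentric.
    sequences:
        Optional per-chromosome base strings (for junction-sequence work);
        when present each must match the declared length.
    """

    chrom_names: tuple
    chrom_lengths: tuple
    centromeres: dict = field(default_factory=dict)
    sequences: Optional[dict] = None

    def __post_init__(self):
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
            cen = self.centromeres.get(name)
            if cen is not None and not (1 <= cen[0] <= cen[1] <= length):
                raise ValueError(f"centromere of {name} outside [1, {length}]")
            if self.sequences is not None and name in self.sequences:
                if len(self.sequences[name]) != length:
                    raise ValueError(f"sequence of {name} does not match its length")

    @property
    def lengths(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class PlantedSV:
    """One ground-truth rearrangement to plant into the reference.

    ``posA``/``posB`` are reference breakpoints. For a deletion the bases
    ``posA..posB`` are removed; for an inversion they are reversed in place;
    for a reciprocal translocation the derivative of ``chromA`` keeps
    ``chromA[1..posA]`` and gains ``chromB[posB+1..]`` (and vice versa).

    ``junction_indels`` gives a signed base count applied on the derived
    strand immediately left of each junction: negative bases are lost,
    positive bases are duplicated.  Deletions have one junction; inversions
    and reciprocal translocations have two (left/der-A first).
    """

    sv_type: str
    chromA: str
    posA: int
    chromB: str
    posB: int
    junction_indels: tuple = (0, 0)

    def __post_init__(self):
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type in ("deletion", "inversion"):
            if self.chromA != self.chromB:
                raise ValueError(f"{self.sv_type} requires chromA == chromB")
            if not self.posA < self.posB:
                raise ValueError(f"{self.sv_type} requires posA < posB")
        if any(abs(k) > 10 for k in self.junction_indels):
            raise ValueError("junction indels are limited to 10 bp")

    @property
    def breakpoints(self) -> list:
        """Reference-space breakpoints as (chrom, pos) pairs."""
        return [(self.chromA, self.posA), (self.chromB, self.posB)]


@dataclass(frozen=True)
class Segment:
    """A run of derived bases copied from one reference strand.

    ``strand == '-'`` means the derived sequence runs from ``ref_end`` down to
    ``ref_start`` (reverse complement).  ``inserted`` marks junction-derived
    duplicated bases, which re-use reference coordinates but are extra copies.
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    strand: str = "+"
    inserted: bool = False

    def __post_init__(self):
        if self.ref_start > self.ref_end:
            raise ValueError("segment with ref_start > ref_end")

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start + 1


class LiftedBase(tuple):
    """(chrom, pos, strand) of the reference base under a derived base."""

    def __new__(cls, chrom, pos, strand, is_junction_insert=False):
        self = super().__new__(cls, (chrom, pos, strand))
        return self

    def __init__(self, chrom, pos, strand, is_junction_insert=False):
        self.is_junction_insert = is_junction_insert

    chrom = property(lambda s: s[0])
    pos = property(lambda s: s[1])
    strand = property(lambda s: s[2])


@dataclass
class RearrangementPlan:
    """Planted SVs plus the derived-genome liftover map they induce.

    ``derived`` maps each derived chromosome name to an ordered list of
    :class:`Segment`; segment order *is* derived coordinate order, so the
    liftover is exact and invertible for every non-junction base.
    """

    reference: ToyReference
    planted: list
    derived: dict

    # -- derived-genome geometry -------------------------------------------

    def derived_lengths(self) -> dict:
        return {name: sum(s.length for s in segs) for name, segs in self.derived.items()}

    def _segment_table(self, chrom: str):
        """Cumulative derived-start positions for binary search."""
        segs = self.derived[chrom]
        starts = np.empty(len(segs), dtype=np.int64)
        run = 1
        for i, s in enumerate(segs):
            starts[i] = run
            run += s.length
        return segs, starts, run - 1  # segments, derived starts, total length

    def lift_to_reference(self, derived_chrom: str, derived_pos: int) -> LiftedBase:
        """Map one derived base to its underlying reference base.

        Junction-duplicated bases are returned with ``is_junction_insert``
        set: they do map to a reference base, but that base already appears
        once elsewhere in the derivative.
        """
        segs, starts, total = self._segment_table(derived_chrom)
        if not 1 <= derived_pos <= total:
            raise ValueError(
                f"position {derived_pos} outside derived {derived_chrom} (1..{total})"
            )
        i = int(np.searchsorted(starts, derived_pos, side="right")) - 1
        seg = segs[i]
        off = derived_pos - int(starts[i])
        if seg.strand == "+":
            ref_pos = seg.ref_start + off
        else:
            ref_pos = seg.ref_end - off
        return LiftedBase(seg.ref_chrom, ref_pos, seg.strand, seg.inserted)

    def lift_from_reference(self, ref_chrom: str, ref_pos: int):
        """Inverse map: (derived_chrom, derived_pos, strand), or None if deleted.

        Junction-duplicated copies are skipped, so every surviving reference
        base has exactly one image.
        """
        for name, segs in self.derived.items():
            run = 1
            for seg in segs:
                if (not seg.inserted and seg.ref_chrom == ref_chrom
                        and seg.ref_start <= ref_pos <= seg.ref_end):
                    if seg.strand == "+":
                        return name, run + (ref_pos - seg.ref_start), "+"
                    return name, run + (seg.ref_end - ref_pos), "-"
                run += seg.length
        return None

    @property
    def liftover(self) -> dict:
        """Per derived chromosome: list of (derived interval, reference interval, strand)."""
        out = {}
        for name, segs in self.derived.items():
            rows, run = [], 1
            for seg in segs:
                rows.append(
                    (
                        (run, run + seg.length - 1),
                        (seg.ref_chrom, seg.ref_start, seg.ref_end),
                        seg.strand,
                        seg.inserted,
                    )
                )
                run += seg.length
            out[name] = rows
        return out

    def derived_sequence(self, chrom: str) -> str:
        """Base string of a derived chromosome (requires reference sequences)."""
        if self.reference.sequences is None:
            raise ValueError("reference carries no sequences")
        parts = []
        for seg in self.derived[chrom]:
            raw = self.reference.sequences[seg.ref_chrom][seg.ref_start - 1 : seg.ref_end]
            parts.append(raw if seg.strand == "+" else raw.translate(_RC)[::-1])
        return "".join(parts)

    def truth_breakpoints(self) -> list:
        """Reference-space breakpoints of every planted SV, for recovery tests."""
        return [(sv.sv_type, sv.breakpoints) for sv in self.planted]

    def to_json(self) -> str:
        payload = {
            "planted": [
                {
                    "sv_type": sv.sv_type,
                    "chromA": sv.chromA, "posA": sv.posA,
                    "chromB": sv.chromB, "posB": sv.posB,
                    "junction_indels": list(sv.junction_indels),
                }
                for sv in self.planted
            ],
            "liftover": {
                name: [
                    {
                        "derived": list(drv), "ref_chrom": ref[0],
                        "ref_start": ref[1], "ref_end": ref[2],
                        "strand": strand, "inserted": inserted,
                    }
                    for drv, ref, strand, inserted in rows
                ]
                for name, rows in self.liftover.items()
            },
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class LibraryModel:
    """Statistical description of one mate-pair sequencing library.

    Defaults emulate an Illumina 5 kb mate-pair preparation sequenced as
    2 x 36 bp: the observed median insert of such libraries is ~5 kb, and a
    fraction of pairs are short-insert paired-end contaminants that escaped
    circularization enrichment (read ends then face inward, FR, instead of
    the mate-pair outward RF convention).
    """

    median_insert: int = 5000
    insert_sd: int = 750
    read_length: int = 36
    n_pairs: int = 10000
    contamination_fraction: float = 0.02
    contaminant_insert: int = 300
    concordant_orientation: str = "RF"
    seed: int = 0

    def __post_init__(self):
        if self.median_insert <= 2 * self.read_length:
            raise ValueError("median_insert must exceed 2 x read_length")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction outside [0, 1]")
        if self.concordant_orientation not in ("RF", "FR"):
            raise ValueError("orientation convention must be 'RF' or 'FR'")


# ---------------------------------------------------------------------------
# plan construction
# ---------------------------------------------------------------------------

def _identity_segments(reference: ToyReference) -> dict:
    return {
        name: [Segment(name, 1, length)]
        for name, length in zip(reference.chrom_names, reference.chrom_lengths)
    }


def _split_before(segs: list, derived_pos: int) -> list:
    """Split the segment list so that ``derived_pos`` starts a segment."""
    out, run = [], 1
    for seg in segs:
        end = run + seg.length - 1
        if run < derived_pos <= end:
            k = derived_pos - run  # bases staying in the left part
            if seg.strand == "+":
                out.append(Segment(seg.ref_chrom, seg.ref_start, seg.ref_start + k - 1,
                                   "+", seg.inserted))
                out.append(Segment(seg.ref_chrom, seg.ref_start + k, seg.ref_end,
                                   "+", seg.inserted))
            else:
                out.append(Segment(seg.ref_chrom, seg.ref_end - k + 1, seg.ref_end,
                                   "-", seg.inserted))
                out.append(Segment(seg.ref_chrom, seg.ref_start, seg.ref_end - k,
                                   "-", seg.inserted))
        else:
            out.append(seg)
        run = end + 1
    return out


def _index_at(segs: list, derived_pos: int) -> int:
    """Index of the segment starting exactly at derived_pos (after _split_before)."""
    run = 0
    for i, seg in enumerate(segs):
        if run + 1 == derived_pos:
            return i
        run += seg.length
    if run + 1 == derived_pos:
        return len(segs)
    raise AssertionError("derived position is not a segment boundary")


def _trim_right(segs: list, n: int) -> list:
    """Drop n derived bases from the right end of a segment list."""
    segs = list(segs)
    while n > 0 and segs:
        seg = segs.pop()
        if seg.length > n:
            if seg.strand == "+":
                segs.append(Segment(seg.ref_chrom, seg.ref_start, seg.ref_end - n,
                                    "+", seg.inserted))
            else:
                segs.append(Segment(seg.ref_chrom, seg.ref_start + n, seg.ref_end,
                                    "-", seg.inserted))
            n = 0
        else:
            n -= seg.length
    return segs


def _dup_right(segs: list, n: int) -> list:
    """Append an inserted copy of the last n derived bases of a segment list."""
    tail, need = [], n
    for seg in reversed(segs):
        take = min(need, seg.length)
        if seg.strand == "+":
            tail.insert(0, Segment(seg.ref_chrom, seg.ref_end - take + 1, seg.ref_end,
                                   "+", True))
        else:
            tail.insert(0, Segment(seg.ref_chrom, seg.ref_start, seg.ref_start + take - 1,
                                   "-", True))
        need -= take
        if need == 0:
            break
    return list(segs) + tail


def _apply_junction_indel(left_part: list, indel: int) -> list:
    if indel < 0:
        return _trim_right(left_part, -indel)
    if indel > 0:
        return _dup_right(left_part, indel)
    return list(left_part)


def _flip(seg: Segment) -> Segment:
    return Segment(seg.ref_chrom, seg.ref_start, seg.ref_end,
                   "-" if seg.strand == "+" else "+", seg.inserted)


def apply_sv_plan(reference: ToyReference, planted: Iterable) -> RearrangementPlan:
    """Apply planted SVs, in list order, to the reference.

    Events are specified in reference coordinates; each breakpoint must still
    be present (not deleted) in the derived genome when its event is applied.
    Events whose breakpoints fall within 1 kb of one another are rejected,
    with a report of every conflicting pair.
    """
    planted = list(planted)
    # breakpoint sanity + pairwise conflict scan
    lengths = reference.lengths
    conflicts = []
    all_bps = []
    for i, sv in enumerate(planted):
        for chrom, pos in sv.breakpoints:
            if chrom not in lengths:
                raise SVPlanError(f"SV {i}: unknown chromosome {chrom!r}")
            if not 1 <= pos <= lengths[chrom]:
                raise SVPlanError(
                    f"SV {i}: breakpoint {chrom}:{pos} outside [1, {lengths[chrom]}]"
                )
            all_bps.append((i, chrom, pos))
    for a in range(len(all_bps)):
        for b in range(a + 1, len(all_bps)):
            ia, ca, pa = all_bps[a]
            ib, cb, pb = all_bps[b]
            if ia != ib and ca == cb and abs(pa - pb) < 1000:
                conflicts.append(
                    f"SV {ia} breakpoint {ca}:{pa} within 1 kb of SV {ib} breakpoint {cb}:{pb}"
                )
    if conflicts:
        raise SVPlanError("overlapping planted SVs:\n" + "\n".join(conflicts))

    derived = _identity_segments(reference)
    plan = RearrangementPlan(reference, planted, derived)

    for sv in planted:
        hitA = plan.lift_from_reference(sv.chromA, sv.posA)
        hitB = plan.lift_from_reference(sv.chromB, sv.posB)
        if hitA is None or hitB is None:
            raise SVPlanError(f"breakpoint of {sv} was deleted by an earlier event")
        if sv.sv_type == "deletion":
            name, da, _ = hitA
            nameB, db, _ = hitB
            if name != nameB:
                raise SVPlanError("deletion endpoints ended up on different derivatives")
            da, db = sorted((da, db))
            segs = _split_before(derived[name], da)
            segs = _split_before(segs, db + 1)
            i, j = _index_at(segs, da), _index_at(segs, db + 1)
            left = _apply_junction_indel(segs[:i], sv.junction_indels[0])
            derived[name] = left + segs[j:]
        elif sv.sv_type == "inversion":
            name, da, _ = hitA
            nameB, db, _ = hitB
            if name != nameB:
                raise SVPlanError("inversion endpoints ended up on different derivatives")
            da, db = sorted((da, db))
            segs = _split_before(derived[name], da)
            segs = _split_before(segs, db + 1)
            i, j = _index_at(segs, da), _index_at(segs, db + 1)
            middle = [_flip(s) for s in reversed(segs[i:j])]
            left = _apply_junction_indel(segs[:i], sv.junction_indels[0])
            body = _apply_junction_indel(left + middle, sv.junction_indels[1])
            derived[name] = body + segs[j:]
        else:  # reciprocal translocation
            nameA, da, _ = hitA
            nameB, db, _ = hitB
            if nameA == nameB:
                raise SVPlanError("translocation breakpoints on one derivative")
            segsA = _split_before(derived[nameA], da + 1)
            segsB = _split_before(derived[nameB], db + 1)
            ia, ib = _index_at(segsA, da + 1), _index_at(segsB, db + 1)
            headA = _apply_junction_indel(segsA[:ia], sv.junction_indels[0])
            headB = _apply_junction_indel(segsB[:ib], sv.junction_indels[1])
            derived[nameA] = headA + segsB[ib:]
            derived[nameB] = headB + segsA[ia:]
    return plan


def lift_to_reference(plan: RearrangementPlan, derived_chrom: str,
                      derived_pos: int) -> LiftedBase:
    """Module-level convenience wrapper around the plan's liftover."""
    return plan.lift_to_reference(derived_chrom, derived_pos)


def demo_reference() -> ToyReference:
    """A two-chromosome, 20 Mb toy genome with centromeres."""
    return ToyReference(
        chrom_names=("chrA", "chrB"),
        chrom_lengths=(12_000_000, 8_000_000),
        centromeres={"chrA": (5_900_000, 6_100_000), "chrB": (3_900_000, 4_100_000)},
    )


def demo_planted() -> list:
    """Four planted events covering every supported rearrangement class.

    One reciprocal translocation, one pericentric inversion (spanning the
    chrA centromere), one paracentric inversion on the chrA p-arm, and one
    15 kb deletion on chrB; all breakpoints are > 1 kb apart.
    """
    return [
        PlantedSV("reciprocal_translocation", "chrA", 9_000_000, "chrB", 6_500_000),
        PlantedSV("inversion", "chrA", 3_000_000, "chrA", 8_000_000),
        PlantedSV("inversion", "chrA", 1_000_000, "chrA", 1_400_000),
        PlantedSV("deletion", "chrB", 1_000_000, "chrB", 1_014_999),
    ]


# ---------------------------------------------------------------------------
# read-pair simulation
# ---------------------------------------------------------------------------

def _lognormal_params(median: float, sd: float):
    # median fixes mu = ln(median); solve sigma so the distribution sd is sd
    mu = np.log(median)
    x = (1.0 + np.sqrt(1.0 + 4.0 * (sd / median) ** 2)) / 2.0
    sigma = np.sqrt(np.log(x))
    return mu, sigma


def _draw_inserts(rng, n, lib: LibraryModel):
    """Truncated log-normal insert lengths: [2 x read_length, 4 x median]."""
    mu, sigma = _lognormal_params(lib.median_insert, lib.insert_sd)
    lo, hi = 2 * lib.read_length, 4 * lib.median_insert
    out = np.rint(rng.lognormal(mu, sigma, size=n)).astype(np.int64)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.lognormal(mu, sigma, size=int(bad.sum()))).astype(np.int64)
        bad = (out < lo) | (out > hi)
    return out


def simulate_pairs(plan: RearrangementPlan, lib: LibraryModel) -> list:
    """Draw mate pairs from the derived genome, reported in reference space.

    Fragment starts are uniform over the derived genome (chromosomes weighted
    by length), insert lengths follow the truncated log-normal of the library
    model, and each 36 bp end is mapped through the liftover — the simulator
    emulates the aligner.  Reads that would straddle a junction (and hence
    fail to align as a full-length match) are dropped together with their
    mate, as they would be in practice.  With probability
    ``contamination_fraction`` a pair is instead a short-insert paired-end
    contaminant with inward-facing (opposite-convention) orientation.
    Deterministic given ``lib.seed``.
    """
    rng = np.random.default_rng(lib.seed)
    names = list(plan.derived.keys())
    tables = {n: plan._segment_table(n) for n in names}
    lengths = np.array([tables[n][2] for n in names], dtype=np.float64)
    for n in names:
        if tables[n][2] <= 3 * lib.median_insert:
            raise ValueError(f"derived chromosome {n} shorter than 3 x median insert")
    weights = lengths / lengths.sum()

    n = lib.n_pairs
    if n == 0:
        return []
    chrom_idx = rng.choice(len(names), size=n, p=weights)
    is_contam = rng.random(n) < lib.contamination_fraction
    inserts = _draw_inserts(rng, n, lib)
    if is_contam.any():
        c = int(is_contam.sum())
        ci = np.rint(rng.normal(lib.contaminant_insert, 0.1 * lib.contaminant_insert,
                                size=c)).astype(np.int64)
        inserts[is_contam] = np.maximum(ci, 2 * lib.read_length)
    u = rng.random(n)

    conv = lib.concordant_orientation           # strands of (left, right) read
    mp_strands = ("-", "+") if conv == "RF" else ("+", "-")
    ct_strands = ("+", "-") if conv == "RF" else ("-", "+")

    rl = lib.read_length
    records = []
    for i in range(n):
        name = names[chrom_idx[i]]
        segs, starts, total = tables[name]
        ins = int(inserts[i])
        s = 1 + int(u[i] * (total - ins + 1))
        e = s + ins - 1
        endpoints = ((s, s + rl - 1), (e - rl + 1, e))
        strands = ct_strands if is_contam[i] else mp_strands
        ends = []
        ok = True
        for (lo, hi), drawn_strand in zip(endpoints, strands):
            j = int(np.searchsorted(starts, lo, side="right")) - 1
            seg = segs[j]
            seg_end = int(starts[j]) + seg.length - 1
            if hi > seg_end or seg.inserted:
                ok = False  # read crosses a junction: unalignable, drop the pair
                break
            off = lo - int(starts[j])
            if seg.strand == "+":
                ref_left = seg.ref_start + off
                strand = drawn_strand
            else:
                # reverse segment: derived rightmost base is the ref leftmost
                ref_left = seg.ref_end - (off + rl - 1)
                strand = "-" if drawn_strand == "+" else "+"
            ends.append(ReadEnd(seg.ref_chrom, ref_left, strand, 60))
        if not ok:
            continue
        records.append(
            ReadPairRecord(
                pair_id=f"sim{i:07d}",
                endA=ends[0],
                endB=ends[1],
                duplicate_flag=False,
                source_tag="contaminant" if is_contam[i] else "matepair",
            )
        )
    return records
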