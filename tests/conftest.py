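"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import pytest

from matesv.calling import CallerConfig, ReadEnd, ReadPairRecord
from matesv.simulator import ToyReference


def mk_pair(pid, chromA, posA, strandA, chromB, posB, strandB,
            mapq=60, dup=False, tag=""):
    return ReadPairRecord(
        pair_id=str(pid),
        endA=ReadEnd(chromA, posA, strandA, mapq),
        endB=ReadEnd(chromB, posB, strandB, mapq),
        duplicate_flag=dup, source_tag=tag)


def rf_pair(pid, chrom, left_pos, span, read_length=36, mapq=60):
    """A concordant RF mate pair with the given outer span."""
    return mk_pair(pid, chrom, left_pos, "-", chrom,
                   left_pos + span - read_length, "+", mapq=mapq)


@pytest.fixture
def tiny_config():
    """Caller config usable on handfuls of pairs."""
    return CallerConfig(min_insert_pairs=1)


@pytest.fixture
def small_ref():
    return ToyReference(
        chrom_names=("chr1", "chr2"),
        chrom_lengths=(10_000, 12_000),
        centromeres={"chr1": (4_500, 5_500), "chr2": (5_500, 6_500)},
    )


# ---------------------------------------------------------------------------
# per-base walk oracle for the rearrangement plan
#
# A derived chromosome is modelled as an explicit list of
# (ref_chrom, ref_pos, strand, inserted) tuples, one per base, built with
# plain list surgery. This is independent of the segment bookkeeping in
# matesv.simulator and feasible only on tiny genomes.
# ---------------------------------------------------------------------------

def _flip(base):
    c, p, s, ins = base
    return (c, p, "-" if s == "+" else "+", ins)


def _oracle_indel(bases, cut, indel):
    """Apply a junction indel on the left side of the junction at index ``cut``."""
    if indel < 0:
        return bases[: cut + indel] + bases[cut:]
    if indel > 0:
        dup = [(c, p, s, True) for c, p, s, _ in bases[cut - indel: cut]]
        return bases[:cut] + dup + bases[cut:]
    return list(bases)


def oracle_apply(ref: ToyReference, planted) -> dict:
    genomes = {
        name: [(name, i + 1, "+", False) for i in range(length)]
        for name, length in zip(ref.chrom_names, ref.chrom_lengths)
    }

    def locate(chrom, pos):
        for name, bases in genomes.items():
            for i, (c, p, _s, ins) in enumerate(bases):
                if not ins and c == chrom and p == pos:
                    return name, i
        raise AssertionError(f"{chrom}:{pos} not found (deleted?)")

    for sv in planted:
        if sv.sv_type == "deletion":
            name, ia = locate(sv.chromA, sv.posA)
            _, ib = locate(sv.chromB, sv.posB)
            ia, ib = sorted((ia, ib))
            bases = genomes[name]
            bases = bases[:ia] + bases[ib + 1:]
            genomes[name] = _oracle_indel(bases, ia, sv.junction_indels[0])
        elif sv.sv_type == "inversion":
            name, ia = locate(sv.chromA, sv.posA)
            _, ib = locate(sv.chromB, sv.posB)
            ia, ib = sorted((ia, ib))
            bases = genomes[name]
            mid = [_flip(b) for b in reversed(bases[ia: ib + 1])]
            bases = bases[:ia] + mid + bases[ib + 1:]
            bases = _oracle_indel(bases, ia, sv.junction_indels[0])
            # left junction indel shifts the right junction index
            shift = sv.junction_indels[0]
            bases = _oracle_indel(bases, ib + 1 + shift, sv.junction_indels[1])
            genomes[name] = bases
        else:  # reciprocal translocation
            nameA, ia = locate(sv.chromA, sv.posA)
            nameB, ib = locate(sv.chromB, sv.posB)
            a, b = genomes[nameA], genomes[nameB]
            newA = _oracle_indel(a[: ia + 1] + b[ib + 1:], ia + 1,
                                 sv.junction_indels[0])
            newB = _oracle_indel(b[: ib + 1] + a[ia + 1:], ib + 1,
                                 sv.junction_indels[1])
            genomes[nameA], genomes[nameB] = newA, newB
    return genomes
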