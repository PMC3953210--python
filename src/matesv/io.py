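"""Readers and writers for the pipeline's on-disk formats.

Internal coordinates are 1-based inclusive; conversions happen only at this
boundary: BED-family outputs (BEDPE, truth BEDPE) are 0-based half-open, SAM
and VCF are 1-based.  All writers are deterministic given the same inputs.

Formats:

* pair table — 10-column TSV (pair_id, chromA, posA, strandA, mapqA, chromB,
  posB, strandB, mapqB, source_tag); a ``source_tag`` of ``duplicate`` marks
  PCR/optical duplicates.
* SAM/BAM — via pysam; duplicate and mapping-quality flags carry through.
* BEDPE — one line per junction with support/type/strand columns.
* VCF 4.2 — BND breakend records for translocation junctions (mates
  cross-referenced by MATEID), SVTYPE=DEL/INV records otherwise.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional

import pandas as pd
import pysam

from matesv.calling import (
    BreakpointInterval,
    ClusterSignature,
    DiscordantCluster,
    ReadEnd,
    ReadPairRecord,
    SVCall,
    chrom_sort_key,
)

PAIR_COLUMNS = ["pair_id", "chromA", "posA", "strandA", "mapqA",
                "chromB", "posB", "strandB", "mapqB", "source_tag"]


# ---------------------------------------------------------------------------
# pair tables
# ---------------------------------------------------------------------------

def write_pairs_tsv(records: Iterable, path) -> None:
    rows = [
        (r.pair_id, r.endA.chrom, r.endA.pos, r.endA.strand, r.endA.mapq,
         r.endB.chrom, r.endB.pos, r.endB.strand, r.endB.mapq,
         "duplicate" if r.duplicate_flag else (r.source_tag or "."))
        for r in records
    ]
    pd.DataFrame(rows, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        line_no = len(records) + 2  # 1-based, after the header line
        if row.posA < 1 or row.posB < 1:
            raise ValueError(f"{path}:{line_no}: coordinate < 1 in 1-based pair table")
        if row.strandA not in "+-" or row.strandB not in "+-":
            raise ValueError(f"{path}:{line_no}: strand must be '+' or '-'")
        tag = "" if pd.isna(row.source_tag) or row.source_tag == "." else str(row.source_tag)
        records.append(ReadPairRecord(
            pair_id=str(row.pair_id),
            endA=ReadEnd(str(row.chromA), int(row.posA), str(row.strandA), int(row.mapqA)),
            endB=ReadEnd(str(row.chromB), int(row.posB), str(row.strandB), int(row.mapqB)),
            duplicate_flag=tag == "duplicate",
            source_tag=tag,
        ))
    return records


def write_pairs_sam(records: Iterable, path, chrom_lengths: dict,
                    read_length: int = 36) -> None:
    """Write pairs as a coordinate-unsorted SAM with proper pair/strand flags."""
    names = sorted(chrom_lengths, key=chrom_sort_key)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(chrom_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            for which, end, mate in (("A", r.endA, r.endB), ("B", r.endB, r.endA)):
                a = pysam.AlignedSegment()
                a.query_name = r.pair_id
                a.query_sequence = "N" * read_length
                a.reference_id = tid[end.chrom]
                a.reference_start = end.pos - 1
                a.mapping_quality = end.mapq
                a.cigartuples = [(0, read_length)]
                a.next_reference_id = tid[mate.chrom]
                a.next_reference_start = mate.pos - 1
                a.is_paired = True
                a.is_read1 = which == "A"
                a.is_read2 = which == "B"
                a.is_reverse = end.strand == "-"
                a.mate_is_reverse = mate.strand == "-"
                a.is_duplicate = r.duplicate_flag
                if r.source_tag:
                    a.set_tag("XS", r.source_tag)
                out.write(a)


def read_pairs_sam(path) -> list:
    """Read a SAM/BAM into pair records (both mates must be present and mapped)."""
    pending: dict = {}
    records = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            end = ReadEnd(aln.reference_name, aln.reference_start + 1,
                          "-" if aln.is_reverse else "+", aln.mapping_quality)
            key = aln.query_name
            if key in pending:
                first_is_A, other, dup, tag = pending.pop(key)
                endA, endB = (other, end) if first_is_A else (end, other)
                records.append(ReadPairRecord(
                    pair_id=key, endA=endA, endB=endB,
                    duplicate_flag=dup or aln.is_duplicate,
                    source_tag=tag or (aln.get_tag("XS") if aln.has_tag("XS") else ""),
                ))
            else:
                pending[key] = (aln.is_read1, end, aln.is_duplicate,
                                aln.get_tag("XS") if aln.has_tag("XS") else "")
    return records


def read_pairs(path, format: Optional[str] = None) -> list:
    """Dispatch on format: 'tsv' or 'sam_bam' (guessed from the suffix)."""
    if format is None:
        s = str(path).lower()
        format = "sam_bam" if s.endswith((".sam", ".bam", ".cram")) else "tsv"
    if format == "tsv":
        return read_pairs_tsv(path)
    if format == "sam_bam":
        return read_pairs_sam(path)
    raise ValueError(f"unknown pair format {format!r}")


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

BEDPE_HEADER = ("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
                "strand1\tstrand2\tsv_type\tsupport\tinversion_class\tspan")


def write_calls_bedpe(calls: Iterable, path) -> None:
    """One BEDPE line per junction (0-based half-open intervals)."""
    lines = [BEDPE_HEADER]
    n = 0
    for call in calls:
        n += 1
        for k, (a, b) in enumerate(call.intervals):
            name = f"SV{n}" if len(call.intervals) == 1 else f"SV{n}_j{k + 1}"
            sig = call.clusters[k].signature if k < len(call.clusters) else None
            s1 = sig.strandA if sig else "."
            s2 = sig.strandB if sig else "."
            lines.append("\t".join(map(str, (
                a.chrom, a.start - 1, a.end, b.chrom, b.start - 1, b.end,
                name, call.support, s1, s2, call.sv_type, call.support,
                call.inversion_class, call.span if call.span is not None else ".",
            ))))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_calls_bedpe(path) -> list:
    """Read junctions back as SVCall objects (one call per BEDPE line)."""
    calls = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 14:
                raise ValueError(f"{path}:{line_no}: expected 14 columns, got {len(parts)}")
            (c1, s1, e1, c2, s2, e2, _name, _score, st1, st2,
             sv_type, support, inv_class, span) = parts
            a = BreakpointInterval(c1, int(s1) + 1, int(e1))
            b = BreakpointInterval(c2, int(s2) + 1, int(e2))
            clusters = []
            if st1 in "+-" and st2 in "+-":
                # keep the strand signature so a re-write is lossless
                clusters = [DiscordantCluster(
                    signature=ClusterSignature(c1, st1, c2, st2), members=[],
                    support=int(support), intervalA=a, intervalB=b)]
            calls.append(SVCall(
                sv_type=sv_type, intervals=[(a, b)], support=int(support),
                span=None if span == "." else int(span),
                inversion_class=inv_class, clusters=clusters,
            ))
    return calls


def write_truth_bedpe(plan, path) -> None:
    """Ground-truth planted SVs as BEDPE (point breakpoints, 0-based half-open)."""
    lines = [("#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tsv_type\t"
              "junction_indels")]
    for i, sv in enumerate(plan.planted, 1):
        lines.append("\t".join(map(str, (
            sv.chromA, sv.posA - 1, sv.posA, sv.chromB, sv.posB - 1, sv.posB,
            f"truth{i}", sv.sv_type, ",".join(map(str, sv.junction_indels)),
        ))))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_plan_json(plan, path) -> None:
    with open(path, "w") as fh:
        fh.write(plan.to_json() + "\n")


# ---------------------------------------------------------------------------
# VCF (writer only)
# ---------------------------------------------------------------------------

_VCF_META = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of supporting read pairs">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of the mate breakend">
##INFO=<ID=CIPOS,Number=2,Type=Integer,Description="Confidence interval around POS">
##INFO=<ID=INVCLASS,Number=1,Type=String,Description="pericentric or paracentric">
"""


def _bnd_alt(keep_here: str, mate_chrom: str, mate_pos: int, keep_mate: str) -> str:
    """Breakend ALT bracket notation from the retained flank of each side."""
    m = f"{mate_chrom}:{mate_pos}"
    if keep_here == "left":  # sequence continues after this base into the mate
        return f"N[{m}[" if keep_mate == "right" else f"N]{m}]"
    return f"]{m}]N" if keep_mate == "left" else f"[{m}[N"


def write_calls_vcf(calls: Iterable, path, chrom_lengths: Optional[dict] = None) -> None:
    """VCF 4.2: BND records for translocation junctions, DEL/INV otherwise."""
    lines = [_VCF_META.rstrip("\n")]
    if chrom_lengths:
        for name in sorted(chrom_lengths, key=chrom_sort_key):
            lines.append(f"##contig=<ID={name},length={int(chrom_lengths[name])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    rows = []
    for n, call in enumerate(calls, 1):
        if call.sv_type in ("deletion", "inversion"):
            (a, b) = call.intervals[0]
            svtype = "DEL" if call.sv_type == "deletion" else "INV"
            info = (f"SVTYPE={svtype};END={b.midpoint};"
                    f"SVLEN={-call.span if svtype == 'DEL' else call.span};"
                    f"SUPPORT={call.support};"
                    f"CIPOS={a.start - a.midpoint},{a.end - a.midpoint}")
            if call.sv_type == "inversion" and call.inversion_class != "NA":
                info += f";INVCLASS={call.inversion_class}"
            rows.append((a.chrom, a.midpoint, f"SV{n}", "N", f"<{svtype}>", info))
        else:
            for k, adj in enumerate(call.adjacencies, 1):
                id1 = f"SV{n}_j{k}a"
                id2 = f"SV{n}_j{k}b"
                alt1 = _bnd_alt(adj.keep1, adj.chrom2, adj.pos2, adj.keep2)
                alt2 = _bnd_alt(adj.keep2, adj.chrom1, adj.pos1, adj.keep1)
                base = f"SVTYPE=BND;SUPPORT={call.support}"
                rows.append((adj.chrom1, adj.pos1, id1, "N", alt1,
                             f"{base};MATEID={id2}"))
                rows.append((adj.chrom2, adj.pos2, id2, "N", alt2,
                             f"{base};MATEID={id1}"))
    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1], r[2]))
    for chrom, pos, vid, ref, alt, info in rows:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_gene_report_tsv(rows: list, path) -> None:
    """Disrupted-gene table (see annotation.disrupted_gene_report)."""
    cols = ["sv_no", "sv_type", "karyotype_token", "breakpoint", "gene",
            "transcript_position", "region", "exon_count", "fusion", "support"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_curation_log(log, path) -> None:
    with open(path, "w") as fh:
        fh.write(log.to_json() + "\n")
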