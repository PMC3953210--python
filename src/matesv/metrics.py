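"""Library QC and cross-platform validation metrics.

* ``spanning_coverage`` — the expected number of mate-pair inserts covering a
  genomic position: n_pairs x median_insert / genome_size.  This is the plain
  formula with no hidden filtering.
* ``chromosome_enrichment`` — how strongly a flow-sorted (or otherwise
  targeted) sequencing fraction is enriched for one chromosome, as the ratio
  of the observed read fraction to the length-proportional expectation; the
  raw observed proportion is also reported since either convention appears in
  practice.
* ``validate_callsets`` — fraction of predicted SV calls confirmed by an
  independent call set under a reciprocal-overlap criterion (breakpoint
  distance for translocations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class CoverageStats:
    n_pairs: int
    median_insert: int
    genome_size: int
    spanning_depth: float


@dataclass(frozen=True)
class EnrichmentResult:
    target: str
    observed_fraction: float
    expected_fraction: float
    fold: float                      # observed / length-proportional expected
    raw_fraction_ratio: float        # observed fraction itself, vs whole library
    per_chromosome_fold: dict = field(default_factory=dict)


@dataclass
class ValidationResult:
    n_predicted: int
    n_confirmed: int
    rate_exact: float                # percent, full precision
    rate: int                        # percent, rounded for display
    matches: list = field(default_factory=list)


def spanning_coverage(n_pairs: int, median_insert: int, genome_size: int) -> CoverageStats:
    """Theoretical genome-wide spanning read-depth of a mate-pair library."""
    if min(n_pairs, median_insert, genome_size) <= 0:
        raise ValueError("all inputs must be positive")
    depth = n_pairs * median_insert / genome_size
    return CoverageStats(n_pairs=n_pairs, median_insert=median_insert,
                         genome_size=genome_size, spanning_depth=depth)


def chromosome_enrichment(read_counts: dict, chrom_lengths: dict,
                          target: str) -> EnrichmentResult:
    """Fold enrichment of one chromosome over its length-proportional share."""
    if set(read_counts) != set(chrom_lengths):
        raise ValueError("read_counts and chrom_lengths cover different chromosomes")
    if target not in read_counts:
        raise ValueError(f"target {target!r} not in the chromosome set")
    total = sum(read_counts.values())
    total_len = sum(chrom_lengths.values())
    if total <= 0:
        raise ValueError("total read count must be positive")
    folds = {}
    for chrom in read_counts:
        obs = read_counts[chrom] / total
        exp = chrom_lengths[chrom] / total_len
        folds[chrom] = obs / exp if exp > 0 else float("nan")
    obs_t = read_counts[target] / total
    exp_t = chrom_lengths[target] / total_len
    return EnrichmentResult(target=target, observed_fraction=obs_t,
                            expected_fraction=exp_t, fold=obs_t / exp_t,
                            raw_fraction_ratio=obs_t, per_chromosome_fold=folds)


# ---------------------------------------------------------------------------
# call-set validation
# ---------------------------------------------------------------------------

_TYPE_FAMILY = {
    "deletion": "deletion",
    "inversion": "inversion",
    "translocation_junction": "translocation",
    "reciprocal_translocation": "translocation",
}


def _call_interval(call):
    """Outer (chrom, start, end) span of an intra-chromosomal call."""
    (a, b) = call.intervals[0]
    lo = min(a.midpoint, b.midpoint)
    hi = max(a.midpoint, b.midpoint)
    return a.chrom, lo, hi


def _reciprocal_overlap(iv1, iv2) -> float:
    c1, s1, e1 = iv1
    c2, s2, e2 = iv2
    if c1 != c2:
        return 0.0
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1 + 1), inter / (e2 - s2 + 1))


def _translocation_match(pred, conf, slack: int) -> bool:
    pj = pred.breakpoints()
    cj = conf.breakpoints()
    for (pa, pb) in pj:
        ok = any(
            pa[0] == ca[0] and pb[0] == cb[0]
            and abs(pa[1] - ca[1]) <= slack and abs(pb[1] - cb[1]) <= slack
            for (ca, cb) in cj
        )
        if not ok:
            return False
    return True


def validate_callsets(predicted: list, confirmed: list,
                      min_reciprocal_overlap: float = 0.5,
                      translocation_slack: int = 10000) -> ValidationResult:
    """Match predicted calls against an independent confirmed call set.

    A predicted call is confirmed iff some confirmed call has the same SV
    type family and chromosome(s) and, for intra-chromosomal calls, a
    reciprocal overlap of at least ``min_reciprocal_overlap``; translocations
    match when both breakpoints agree within ``translocation_slack`` bp.
    The rate is reported rounded to the nearest integer percent, with the
    exact fraction retained.
    """
    if not predicted:
        raise ValueError("validation rate undefined for an empty predicted set")
    matches = []
    n_confirmed = 0
    for i, pred in enumerate(predicted):
        fam = _TYPE_FAMILY[pred.sv_type]
        best: Optional[dict] = None
        for j, conf in enumerate(confirmed):
            if _TYPE_FAMILY[conf.sv_type] != fam:
                continue
            if fam == "translocation":
                if _translocation_match(pred, conf, translocation_slack):
                    best = {"confirmed_index": j, "overlap": 1.0}
                    break
            else:
                ov = _reciprocal_overlap(_call_interval(pred), _call_interval(conf))
                if ov >= min_reciprocal_overlap and (best is None or ov > best["overlap"]):
                    best = {"confirmed_index": j, "overlap": ov}
        confirmed_flag = best is not None
        n_confirmed += confirmed_flag
        matches.append({
            "predicted_index": i,
            "sv_type": pred.sv_type,
            "confirmed": confirmed_flag,
            **(best or {"confirmed_index": None, "overlap": 0.0}),
        })
    exact = 100.0 * n_confirmed / len(predicted)
    return ValidationResult(n_predicted=len(predicted), n_confirmed=n_confirmed,
                            rate_exact=exact, rate=round(exact), matches=matches)
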