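"""Insert statistics, pair classification, clustering, refinement, junctions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from matesv.calling import (
    CallerConfig,
    DiscordantClass,
    InsertStats,
    InsufficientPairsError,
    JunctionMatchError,
    canonical_ends,
    classify_pair,
    cluster_discordant,
    estimate_insert_stats,
    junction_delta,
    refine_intervals,
)

from conftest import mk_pair, rf_pair

HSETTINGS = settings(deadline=None, derandomize=True, max_examples=60)


class TestInsertStats:
    def test_median_and_cutoff_rule(self, tiny_config):
        pairs = [rf_pair(i, "chr1", 1000 * i, s)
                 for i, s in enumerate((4900, 5012, 5100))]
        stats = estimate_insert_stats(pairs, tiny_config)
        assert stats.median_insert == 5012
        assert stats.cutoff == 10024

    def test_identical_spans_zero_mad(self, tiny_config):
        pairs = [rf_pair(i, "chr1", 1000 * i, 4321) for i in range(5)]
        stats = estimate_insert_stats(pairs, tiny_config)
        assert (stats.median_insert, stats.mad) == (4321, 0)

    def test_too_few_pairs_is_hard_error(self):
        pairs = [rf_pair(1, "chr1", 100, 5000)]
        with pytest.raises(InsufficientPairsError, match="1 usable"):
            estimate_insert_stats(pairs, CallerConfig())

    def test_override_rescues_small_input(self):
        cfg = CallerConfig(median_override=5012)
        stats = estimate_insert_stats([], cfg)
        assert (stats.median_insert, stats.cutoff) == (5012, 10024)

    def test_discordant_pairs_excluded_from_estimate(self, tiny_config):
        pairs = [rf_pair(i, "chr1", 1000 * i, 5000) for i in range(4)]
        pairs.append(rf_pair(9, "chr1", 50_000, 90_000))      # > 10x nominal
        pairs.append(mk_pair(10, "chr1", 100, "+", "chr1", 5064, "-"))  # everted
        stats = estimate_insert_stats(pairs, tiny_config)
        assert (stats.median_insert, stats.n_used) == (5000, 4)


class TestClassifyPair:
    STATS = InsertStats.from_median(5012)  # cutoff 10024

    def test_interchromosomal(self):
        assert classify_pair(mk_pair(1, "chr2", 100, "-", "chr7", 200, "+"),
                             self.STATS) is DiscordantClass.INTERCHROMOSOMAL

    def test_long_span(self):
        p = rf_pair(1, "chr1", 1000, 25_000)
        assert classify_pair(p, self.STATS) is DiscordantClass.LONG_SPAN

    def test_concordant(self):
        assert classify_pair(rf_pair(1, "chr1", 1000, 5000),
                             self.STATS) is DiscordantClass.CONCORDANT

    def test_same_strand_is_orientation_aberrant(self):
        p = mk_pair(1, "chr1", 1000, "-", "chr1", 6000, "-")
        assert classify_pair(p, self.STATS) is DiscordantClass.ORIENTATION_ABERRANT

    def test_precedence_duplicate_and_quality(self):
        dup = mk_pair(1, "chr2", 100, "-", "chr7", 200, "+", dup=True)
        assert classify_pair(dup, self.STATS) is DiscordantClass.DUPLICATE
        lowq = mk_pair(2, "chr2", 100, "-", "chr7", 200, "+", mapq=5)
        assert classify_pair(lowq, self.STATS) is DiscordantClass.LOW_QUALITY

    def test_order_invariance(self):
        p = mk_pair(1, "chr7", 200, "+", "chr2", 100, "-")
        q = mk_pair(1, "chr2", 100, "-", "chr7", 200, "+")
        assert classify_pair(p, self.STATS) is classify_pair(q, self.STATS)


def brute_force_clusters(pairs, cutoff):
    """O(n^2) single-linkage oracle over the pairwise linkage graph."""
    import networkx as nx

    sigs = {}
    for p in pairs:
        a, b = canonical_ends(p)
        sigs.setdefault((a.chrom, a.strand, b.chrom, b.strand), []).append((a.pos, b.pos, p))
    partitions = set()
    for rows in sigs.values():
        g = nx.Graph()
        g.add_nodes_from(range(len(rows)))
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if (abs(rows[i][0] - rows[j][0]) <= cutoff
                        and abs(rows[i][1] - rows[j][1]) <= cutoff):
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            partitions.add(frozenset(rows[i][2].pair_id for i in comp))
    return partitions


class TestClustering:
    STATS = InsertStats.from_median(5000)  # cutoff 10000

    def _inter_pairs(self, n):
        return [mk_pair(i, "chr2", 8_000_000 + 300 * i, "-",
                        "chr7", 135_000_000 + 300 * i, "+") for i in range(n)]

    def test_six_pairs_retained_five_discarded(self):
        six = cluster_discordant(self._inter_pairs(6), self.STATS, min_support=6)
        assert len(six) == 1 and six[0].support == 6
        five = cluster_discordant(self._inter_pairs(5), self.STATS, min_support=6)
        assert five == []

    def test_empty_input(self):
        assert cluster_discordant([], self.STATS) == []

    def test_duplicates_removed_before_support(self):
        pairs = self._inter_pairs(5)
        pairs.append(mk_pair(99, "chr2", 8_000_000, "-", "chr7", 135_000_000, "+"))
        # 6 records but only 5 distinct coordinate/strand combinations
        assert cluster_discordant(pairs, self.STATS, min_support=6) == []

    def test_signatures_never_mix(self):
        pairs = self._inter_pairs(6)
        flipped = [mk_pair(100 + i, "chr2", 8_000_000 + 300 * i, "+",
                           "chr7", 135_000_000 + 300 * i, "-") for i in range(6)]
        clusters = cluster_discordant(pairs + flipped, self.STATS, min_support=6)
        assert len(clusters) == 2
        assert {tuple(c.signature) for c in clusters} == {
            ("chr2", "-", "chr7", "+"), ("chr2", "+", "chr7", "-")}

    @given(st.integers(0, 2**31 - 1), st.integers(1, 300))
    @HSETTINGS
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        pairs = []
        for i in range(n):
            ca, cb = rng.choice(["chr1", "chr2"], size=2)
            sa, sb = rng.choice(["+", "-"], size=2)
            pairs.append(mk_pair(i, ca, int(rng.integers(1, 100_000)), sa,
                                 cb, int(rng.integers(1, 100_000)), sb))
        clusters = cluster_discordant(pairs, self.STATS, min_support=1)
        got = {frozenset(m.pair_id for m in c.members) for c in clusters}
        assert got == brute_force_clusters(pairs, self.STATS.cutoff)


class TestRefinement:
    STATS = InsertStats.from_median(5000)  # cutoff 10000

    def test_single_member_geometry(self):
        # one read at 1,000 pointing right: the junction base can be no
        # earlier than the read's innermost aligned base (1,035 for a 36-mer)
        # and no farther than one insert cutoff from its outer edge
        pairs = [mk_pair(1, "chr2", 1000, "-", "chr7", 99_000, "+")]
        cluster = cluster_discordant(pairs, self.STATS, min_support=1)[0]
        refined = refine_intervals(cluster, self.STATS)
        assert refined.intervalA.start == 1035
        assert refined.intervalA.end == 11_000
        assert refined.intervalA.width <= self.STATS.cutoff

    def test_width_non_increasing_with_support(self):
        rng = np.random.default_rng(0)
        junction = 50_000
        pairs = []
        for i in range(30):
            insert = int(rng.integers(4000, 5500))
            off = int(rng.integers(36, insert - 36))
            pairs.append(mk_pair(i, "chr2", junction - off, "-",
                                 "chr7", 135_000_000 + (insert - off) - 36, "+"))
        widths = []
        for k in range(1, 31):
            cluster = cluster_discordant(pairs[:k], self.STATS, min_support=1)
            assert len(cluster) == 1
            refined = refine_intervals(cluster[0], self.STATS)
            widths.append(refined.intervalA.width)
            assert junction in range(refined.intervalA.start, refined.intervalA.end + 1)
        assert all(w2 <= w1 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] < widths[0]

    def test_left_pointing_side_mirrored(self):
        pairs = [mk_pair(1, "chr2", 1000, "-", "chr7", 99_000, "+")]
        cluster = cluster_discordant(pairs, self.STATS, min_support=1)[0]
        refined = refine_intervals(cluster, self.STATS)
        # '+' read at 99,000 points left: junction within cutoff of its end
        assert refined.intervalB.end == 99_000
        assert refined.intervalB.start == 99_000 + 35 - 10_000

    def test_junction_straddling_contaminant_outvoted(self):
        # honest inversion-junction members bound the junction pair (50,000 /
        # 250,000); one short-insert contaminant straddling the right-hand
        # junction mimics the signature but its reads sit a few hundred bp on
        # the wrong sides, and its implied insert (~300 bp vs ~5 kb) gives it
        # away: the refined intervals must still contain both true junctions
        pairs = []
        rng = np.random.default_rng(1)
        for i in range(12):
            insert = int(rng.integers(4200, 5600))
            off = int(rng.integers(40, insert - 80))
            pairs.append(mk_pair(i, "chr1", 50_000 - off, "-",
                                 "chr1", 250_000 - (insert - off) + 36, "-"))
        pairs.append(mk_pair(99, "chr1", 50_000 + 80, "-", "chr1", 250_000 + 150, "-"))
        clusters = cluster_discordant(pairs, self.STATS, min_support=6)
        assert len(clusters) == 1 and clusters[0].support == 13
        refined = refine_intervals(clusters[0], self.STATS)
        assert refined.intervalA.start <= 50_000 <= refined.intervalA.end
        assert refined.intervalB.start <= 250_000 <= refined.intervalB.end

    def test_empty_cluster_rejected(self):
        from matesv.calling import ClusterSignature, DiscordantCluster
        c = DiscordantCluster(ClusterSignature("chr1", "-", "chr2", "+"), [], 0)
        with pytest.raises(ValueError):
            refine_intervals(c, self.STATS)


class TestJunctionDelta:
    LEFT = "ACGTACGTTGACCGGTAAGCTTGCAACGT"
    RIGHT = "TTGCAGGCATCGATTAACCGGGTACGATC"

    def test_balanced(self):
        assert junction_delta(self.LEFT, self.RIGHT, self.LEFT + self.RIGHT) == (
            0, "balanced")

    def test_one_base_lost(self):
        junction = self.LEFT + self.RIGHT[1:]
        assert junction_delta(self.LEFT, self.RIGHT, junction) == (-1, "1 bp lost")

    def test_one_base_duplicated(self):
        junction = self.LEFT + self.LEFT[-1] + self.RIGHT
        assert junction_delta(self.LEFT, self.RIGHT, junction) == (1, "1 bp duplicated")

    def test_unrelated_junction_rejected(self):
        with pytest.raises(JunctionMatchError, match="not a junction"):
            junction_delta(self.LEFT, self.RIGHT, "GGGGGGGGGGGGGGGGGGGGGGGGG")

    @given(st.integers(-5, 5), st.integers(0, 2**31 - 1))
    @HSETTINGS
    def test_recovers_planted_indel(self, indel, seed):
        rng = np.random.default_rng(seed)
        left = "".join(rng.choice(list("ACGT"), size=40))
        right = "".join(rng.choice(list("ACGT"), size=40))
        if indel < 0:
            junction = left + right[-indel:]
        else:
            junction = left + left[len(left) - indel:] + right
        delta, _ = junction_delta(left, right, junction)
        assert delta == indel

    def test_simulated_junction_sequence_round_trip(self):
        # plant a translocation losing 1 bp, rebuild the derived sequence and
        # reconcile the junction window against the reference flanks
        from matesv.simulator import PlantedSV, ToyReference, apply_sv_plan

        rng = np.random.default_rng(123)
        seqs = {"c1": "".join(rng.choice(list("ACGT"), size=5000)),
                "c2": "".join(rng.choice(list("ACGT"), size=5000))}
        ref = ToyReference(("c1", "c2"), (5000, 5000), sequences=seqs)
        sv = PlantedSV("reciprocal_translocation", "c1", 2500, "c2", 3000,
                       junction_indels=(-1, 0))
        plan = apply_sv_plan(ref, [sv])
        der = plan.derived_sequence("c1")
        ref_left = seqs["c1"][2460:2500]   # c1:2461..2500, the balanced left flank
        ref_right = seqs["c2"][3000:3040]  # c2:3001..3040, the right flank
        # derived junction amplicon sharing its first base with ref_left and
        # its last with ref_right: 79 bp because one base was lost
        window = der[2460:2539]
        delta, desc = junction_delta(ref_left, ref_right, window)
        assert (delta, desc) == (-1, "1 bp lost")
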