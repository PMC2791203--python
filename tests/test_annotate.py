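"""Gene windows, Fisher enrichment and interaction-ratio statistics."""

import math

import numpy as np
import pytest

from cooccur.annotate import (
    EnrichmentResult,
    GeneRecord,
    InteractionTable,
    PeakGeneSets,
    fisher_enrichment,
    genes_in_window,
    interaction_pairs,
    interaction_ratio,
    peak_gene_sets,
    random_loci_control,
)
from cooccur.grid import ArmDefinition
from cooccur.peaks import Peak, RankedPeakList


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def gene(gid, chrom, mid, half=500):
    return GeneRecord(gid, chrom, mid - half, mid + half)


class TestGenesInWindow:
    def test_boundary_inclusive(self):
        genes = [gene("at_peak", "1", 5_000_000), gene("at_sigma", "1", 5_000_000 + 333_333)]
        found = genes_in_window(("1", "q", 5_000_000), 333_333, genes)
        assert found == {"at_peak", "at_sigma"}

    def test_outside_window_and_wrong_chromosome_excluded(self):
        sigma = 1_000_000 // 3
        genes = [gene("far", "1", 5_400_000), gene("other", "2", 5_000_000)]
        assert genes_in_window(("1", "q", 5_000_000), sigma, genes) == set()

    def test_matches_linear_scan_oracle(self, rng):
        genes = [gene(f"g{i}", "1", int(p)) for i, p in
                 enumerate(rng.integers(0, 10_000_000, 100))]
        locus = ("1", "q", 5_000_000)
        sigma = 700_000
        expected = {g.gene_id for g in genes if abs(g.midposition - 5_000_000) <= sigma}
        assert genes_in_window(locus, sigma, genes) == expected

    def test_monotone_in_sigma(self, rng):
        genes = [gene(f"g{i}", "1", int(p)) for i, p in
                 enumerate(rng.integers(0, 10_000_000, 50))]
        locus = ("1", "q", 5_000_000)
        small = genes_in_window(locus, 200_000, genes)
        large = genes_in_window(locus, 2_000_000, genes)
        assert small <= large


class TestFisherEnrichment:
    def _run(self, a, b, c, d):
        universe = {f"u{i}" for i in range(a + b + c + d)}
        ordered = sorted(universe)
        selected = set(ordered[: a + b])
        category = set(ordered[:a]) | set(ordered[a + b : a + b + c])
        return fisher_enrichment(selected, category, universe)

    def test_balanced_table_p_one(self):
        assert self._run(1, 1, 1, 1).p_value == pytest.approx(1.0)

    def test_diagonal_table(self):
        assert self._run(2, 0, 0, 2).p_value == pytest.approx(1 / 3)

    def test_category_equals_universe(self):
        universe = {"a", "b", "c", "d"}
        res = fisher_enrichment({"a", "b"}, set(universe), universe)
        assert res.p_value == pytest.approx(1.0)

    def test_category_outside_universe_dropped(self):
        universe = {"a", "b", "c", "d"}
        res = fisher_enrichment({"a"}, {"a", "zzz"}, universe)
        assert res.table[0][0] == 1
        assert sum(res.table[0]) + sum(res.table[1]) == 4

    def test_agrees_with_enumeration_on_sampled_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 5, 4))
            if a + b + c + d == 0:
                continue
            res = self._run(a, b, c, d)
            assert res.p_value == pytest.approx(fisher_two_sided_oracle(a, b, c, d), abs=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), set(), set())


class TestInteractionPairs:
    def test_threshold_strict_and_cross_locus_only(self):
        table = InteractionTable([("x", "y", 0.95), ("x", "w", 0.9), ("a", "b", 0.99)])
        pairs = interaction_pairs({"x", "a", "b"}, {"y", "w"}, table, threshold=0.9)
        # (x,w) at exactly 0.9 fails the strict threshold; (a,b) is within-locus
        assert pairs == {frozenset(("x", "y"))}

    def test_matches_nested_loop_oracle(self, rng):
        genes_a = {f"a{i}" for i in range(8)}
        genes_b = {f"b{i}" for i in range(8)}
        records = []
        for ga in genes_a:
            for gb in genes_b:
                if rng.random() < 0.4:
                    records.append((ga, gb, float(rng.random())))
        table = InteractionTable(records)
        got = interaction_pairs(genes_a, genes_b, table, 0.5)
        expected = {
            frozenset((ga, gb))
            for ga, gb, c in records
            if c > 0.5
        }
        assert got == expected

    def test_undirected_storage(self):
        t = InteractionTable([("a", "b", 0.3), ("b", "a", 0.8)])
        assert t.confidence("a", "b") == 0.8
        assert len(t) == 1


def gs(peak_id, genes_a, genes_b):
    p = Peak("1", "q", 0, "2", "q", 0, 1.0, "loss-loss", 2e6, rank=peak_id)
    return PeakGeneSets(p, set(genes_a), set(genes_b))


class TestInteractionRatio:
    def test_no_qualifying_pairs(self):
        ratio, interacting, all_genes = interaction_ratio(
            [gs(1, {"a"}, {"b"})], InteractionTable(), 0.9
        )
        assert ratio == 0.0 and interacting == set() and len(all_genes) == 2

    def test_hand_count(self):
        # 20 genes total, 4 of them in qualifying cross-locus pairs -> 0.2
        sets = [
            gs(1, {f"a{i}" for i in range(5)}, {f"b{i}" for i in range(5)}),
            gs(2, {f"c{i}" for i in range(5)}, {f"d{i}" for i in range(5)}),
        ]
        table = InteractionTable([("a0", "b0", 0.95), ("c1", "d2", 0.99)])
        ratio, interacting, all_genes = interaction_ratio(sets, table, 0.9)
        assert len(all_genes) == 20 and len(interacting) == 4
        assert ratio == pytest.approx(0.2)

    def test_set_semantics_across_duplicate_peaks(self):
        sets = [gs(1, {"x"}, {"y"}), gs(2, {"x"}, {"y"})]
        table = InteractionTable([("x", "y", 0.95)])
        ratio, interacting, all_genes = interaction_ratio(sets, table, 0.9)
        assert len(all_genes) == 2 and len(interacting) == 2
        assert ratio == 1.0

    def test_order_invariance(self):
        sets = [gs(1, {"a"}, {"b"}), gs(2, {"c"}, {"d"})]
        table = InteractionTable([("a", "b", 0.95)])
        r1, _, _ = interaction_ratio(sets, table, 0.9)
        r2, _, _ = interaction_ratio(sets[::-1], table, 0.9)
        assert r1 == r2

    def test_empty_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="no genes"):
            interaction_ratio([gs(1, set(), set())], InteractionTable(), 0.9)


class TestRandomLociControl:
    @pytest.fixture
    def setup(self, rng):
        arms = [ArmDefinition(str(c), "q", 0, 20_000_000) for c in range(1, 5)]
        genes = [
            gene(f"g{c}_{i}", str(c), int(p))
            for c in range(1, 5)
            for i, p in enumerate(rng.integers(400_000, 19_600_000, 60))
        ]
        peaks = RankedPeakList("loss-loss", 2e6, 5, [
            Peak("1", "q", 5_000_000, "2", "q", 7_000_000, 3.0, "loss-loss", 2e6, rank=1),
            Peak("3", "q", 9_000_000, "4", "q", 4_000_000, 2.0, "loss-loss", 2e6, rank=2),
        ])
        return arms, genes, peaks

    def test_same_seed_reproducible(self, setup, rng):
        arms, genes, peaks = setup
        records = [(f"g1_{i}", f"g2_{j}", 0.95) for i in range(10) for j in range(10)]
        table = InteractionTable(records)
        out1 = random_loci_control(peaks, arms, genes, table, n_random=20, seed=7)
        out2 = random_loci_control(peaks, arms, genes, table, n_random=20, seed=7)
        assert out1[0] == out2[0]
        assert out1[1].p_value == out2[1].p_value
        out3 = random_loci_control(peaks, arms, genes, table, n_random=20, seed=8)
        assert out1[0] != out3[0] or out1[1].table != out3[1].table

    def test_empty_interactions_p_one(self, setup):
        arms, genes, peaks = setup
        ratio_rand, res = random_loci_control(
            peaks, arms, genes, InteractionTable(), n_random=10, seed=3
        )
        assert ratio_rand == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_arm_shorter_than_window_rejected(self, setup):
        arms, genes, peaks = setup
        short = arms + [ArmDefinition("9", "p", 0, 100_000)]
        with pytest.raises(ValueError, match="shorter"):
            random_loci_control(peaks, short, genes, InteractionTable(), seed=1)

    def test_random_ratio_near_analytic_expectation(self, setup):
        """At uniform interaction density d, a gene interacts with a random
        cross-locus partner set of size m with probability 1-(1-d)^m; the
        pooled random ratio over seeds should sit within 3 binomial SEs."""
        arms, genes, peaks = setup
        d = 0.3
        rng = np.random.default_rng(99)
        all_ids = [g.gene_id for g in genes]
        records = [
            (a, b, 0.95)
            for i, a in enumerate(all_ids)
            for b in all_ids[i + 1 :]
            if rng.random() < d
        ]
        table = InteractionTable(records)
        ratios = []
        for seed in range(20):
            r, _ = random_loci_control(
                peaks, arms, genes, table, threshold=0.9, n_random=5, seed=seed
            )
            ratios.append(r)
        mean_ratio = np.mean(ratios)
        # windows hold ~2 genes (60 genes / 20 Mb, 667 kb window); a partner
        # set of ~2 genes gives per-gene interaction prob ~1-(1-d)^2
        expect = 1 - (1 - d) ** 2
        se = math.sqrt(expect * (1 - expect) / (20 * 5 * 4))
        assert abs(mean_ratio - expect) < max(3 * se, 0.25)


def test_enrichment_result_margins_consistent():
    res = fisher_enrichment({"a", "b"}, {"b", "c"}, {"a", "b", "c", "d"})
    (a, b), (c, d) = res.table
    assert a + b == 2 and a + c == 2 and a + b + c + d == 4
    assert isinstance(res, EnrichmentResult)


def test_peak_gene_sets_windows_both_loci():
    genes = [gene("ga", "1", 5_000_000), gene("gb", "2", 7_000_000)]
    p = Peak("1", "q", 5_000_000, "2", "q", 7_000_000, 1.0, "loss-loss", 2e6, rank=1)
    sets = peak_gene_sets([p], 333_333, genes)
    assert sets[0].genes_a == {"ga"} and sets[0].genes_b == {"gb"}
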