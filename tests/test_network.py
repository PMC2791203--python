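"""Locus clustering, graph construction and core pruning."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from cooccur.network import (
    OFF_ARM_DISTANCE,
    build_graph,
    cluster_loci,
    locus_distance_matrix,
    prune_core,
)
from cooccur.peaks import Peak


def loci_on(arm_positions):
    """[('1','q',pos), ...] from {(chrom, arm): [pos, ...]}."""
    return [(c, a, p) for (c, a), ps in arm_positions.items() for p in ps]


class TestDistanceMatrix:
    def test_same_arm_absolute_difference(self):
        dm = locus_distance_matrix([("1", "q", 3_000_000), ("1", "q", 8_000_000)])
        assert dm.D[0, 1] == 5_000_000

    def test_off_arm_constant(self):
        dm = locus_distance_matrix([("9", "p", 100), ("17", "p", 100)])
        assert dm.D[0, 1] == 1e8

    def test_pq_arms_of_one_chromosome_are_off_arm(self):
        dm = locus_distance_matrix([("1", "p", 100), ("1", "q", 100)])
        assert dm.D[0, 1] == OFF_ARM_DISTANCE

    def test_diagonal_zero_and_symmetric(self):
        dm = locus_distance_matrix(loci_on({("1", "q"): [0, 5_000_000], ("2", "q"): [7]}))
        assert np.all(np.diag(dm.D) == 0)
        np.testing.assert_array_equal(dm.D, dm.D.T)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            locus_distance_matrix([])


class TestClusterLoci:
    def test_two_clusters_by_hand(self):
        dm = locus_distance_matrix(loci_on({("1", "q"): [0, 5_000_000, 30_000_000]}))
        labels = cluster_loci(dm, cutoff_bp=10_000_000)
        assert labels[0] == labels[1] != labels[2]

    def test_single_linkage_chaining(self):
        dm = locus_distance_matrix(loci_on({("1", "q"): [0, 8_000_000, 16_000_000]}))
        labels = cluster_loci(dm, cutoff_bp=10_000_000)
        assert len(set(labels)) == 1

    def test_cross_arm_loci_never_merge(self):
        dm = locus_distance_matrix(loci_on({("1", "q"): [0], ("2", "q"): [0], ("1", "p"): [0]}))
        labels = cluster_loci(dm, cutoff_bp=10_000_000)
        assert len(set(labels)) == 3

    def test_strict_cutoff_boundary(self):
        dm = locus_distance_matrix(loci_on({("1", "q"): [0, 10_000_000]}))
        # distance exactly at the cutoff does not merge (strict <)
        assert len(set(cluster_loci(dm, cutoff_bp=10_000_000))) == 2
        assert len(set(cluster_loci(dm, cutoff_bp=10_000_001))) == 1

    def test_matches_scipy_single_linkage(self, rng):
        positions = {
            ("1", "q"): sorted(int(p) for p in rng.integers(0, 80_000_000, 12)),
            ("2", "q"): sorted(int(p) for p in rng.integers(0, 80_000_000, 9)),
            ("3", "p"): sorted(int(p) for p in rng.integers(0, 50_000_000, 5)),
        }
        loci = loci_on(positions)
        dm = locus_distance_matrix(loci)
        ours = cluster_loci(dm, cutoff_bp=10_000_000)
        Z = linkage(squareform(dm.D, checks=False), method="single")
        scipy_labels = fcluster(Z, t=10_000_000 - 0.5, criterion="distance")
        # same partition up to label names
        pairing = {}
        for a, b in zip(ours, scipy_labels):
            pairing.setdefault(a, b)
            assert pairing[a] == b
        assert len(set(ours)) == len(set(scipy_labels))

    def test_input_order_invariance(self, rng):
        loci = loci_on({("1", "q"): [0, 4_000_000, 30_000_000], ("2", "q"): [1_000_000]})
        dm = locus_distance_matrix(loci)
        base = dict(zip(loci, cluster_loci(dm, 10_000_000)))
        perm = [loci[i] for i in rng.permutation(len(loci))]
        shuffled = dict(zip(perm, cluster_loci(locus_distance_matrix(perm), 10_000_000)))
        assert base == shuffled

    def test_cutoff_must_stay_below_off_arm_constant(self):
        dm = locus_distance_matrix([("1", "q", 0)])
        with pytest.raises(ValueError):
            cluster_loci(dm, cutoff_bp=OFF_ARM_DISTANCE)


def pk(locus_a, locus_b, rank=None, score=1.0):
    (ca, aa, pa), (cb, ab, pb) = locus_a, locus_b
    return Peak(ca, aa, pa, cb, ab, pb, score, "loss-loss", 2e6, rank=rank)


class TestBuildGraph:
    @pytest.fixture
    def clustered(self):
        loci = [("1", "q", 0), ("1", "q", 2_000_000), ("2", "q", 0), ("3", "q", 0)]
        assignment = np.array([0, 0, 1, 2])
        return loci, assignment

    def test_edge_support_counts(self, clustered):
        loci, assignment = clustered
        pairs = [
            pk(loci[0], loci[2], rank=1),
            pk(loci[1], loci[2], rank=2),
            pk(loci[0], loci[2], rank=3),
        ]
        G = build_graph(loci, assignment, pairs)
        assert G.number_of_edges() == 1
        assert G[0][1]["support"] == 3
        assert G.nodes[0]["best_rank"] == 1

    def test_within_cluster_pair_dropped_and_counted(self, clustered):
        loci, assignment = clustered
        pairs = [pk(loci[0], loci[1], rank=1), pk(loci[2], loci[3], rank=2)]
        G = build_graph(loci, assignment, pairs)
        assert not G.has_edge(0, 0)
        assert G.graph["within_cluster_pairs"] == 1
        assert G.number_of_edges() == 1

    def test_support_conservation(self, clustered, rng):
        loci, assignment = clustered
        pairs = [
            pk(loci[int(i)], loci[int(j)], rank=r + 1)
            for r, (i, j) in enumerate(
                rng.integers(0, 4, (30, 2))
            )
            if i != j
        ]
        G = build_graph(loci, assignment, pairs)
        total = sum(s for _, _, s in G.edges(data="support")) + G.graph["within_cluster_pairs"]
        assert total == len(pairs)

    def test_empty_cooccurrences_gives_nodes_only(self, clustered):
        loci, assignment = clustered
        G = build_graph(loci, assignment, [])
        assert G.number_of_nodes() == 3 and G.number_of_edges() == 0

    def test_unassigned_locus_rejected(self, clustered):
        loci, assignment = clustered
        with pytest.raises(ValueError, match="no cluster assignment"):
            build_graph(loci, assignment, [pk(("9", "p", 0), loci[0])])

    def test_singleton_cutoff_reduces_to_raw_pairs(self):
        loci = [("1", "q", 0), ("2", "q", 0), ("3", "q", 0)]
        dm = locus_distance_matrix(loci)
        assignment = cluster_loci(dm, cutoff_bp=1)  # below any pairwise distance
        pairs = [pk(loci[0], loci[1], 1), pk(loci[1], loci[2], 2)]
        G = build_graph(loci, assignment, pairs)
        assert G.number_of_nodes() == 3
        assert G.number_of_edges() == 2


class TestPruneCore:
    def _graph(self, supports):
        import networkx as nx

        G = nx.Graph(within_cluster_pairs=0)
        for i, s in enumerate(supports):
            G.add_edge(2 * i, 2 * i + 1, support=s)
        return G

    def test_boundary_at_five_percent_of_500(self):
        G = self._graph([25, 24])
        core = prune_core(G, total_cooccurrences=500, min_fraction=0.05)
        assert core.number_of_edges() == 1
        (u, v, s), = core.edges(data="support")
        assert s == 25

    def test_all_below_threshold_empties_graph(self):
        core = prune_core(self._graph([1, 2, 3]), 500, 0.05)
        assert core.number_of_nodes() == 0

    def test_isolated_nodes_removed(self):
        G = self._graph([30, 5])
        core = prune_core(G, 500, 0.05)
        assert set(core.nodes) == {0, 1}

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            prune_core(self._graph([5]), 500, 0.0)
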