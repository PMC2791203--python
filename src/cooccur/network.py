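"""Co-occurrence networks: cluster loci into nodes, link them by support.

The loci of a top-N peak list are clustered by genomic distance (same-arm
distance = |bp difference|, different arms = a large constant, 1e8 bp) with
single-linkage agglomeration cut strictly below a distance cutoff (default
10 Mb).  Each cluster becomes a node; an edge links two nodes whenever at
least one co-occurrence pairs a locus of one with a locus of the other,
weighted by the number of such co-occurrences.  A core network keeps only
edges supported by at least a set fraction of the co-occurrence list.

Single-linkage clusters at a strict threshold are exactly the connected
components of the graph whose edges are locus pairs closer than the cutoff;
the implementation uses that identity directly.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import connected_components
from dataclasses import dataclass, field

from cooccur.peaks import Peak

OFF_ARM_DISTANCE = 10**8
"""Distance assigned to locus pairs on different chromosome arms (bp)."""

DEFAULT_CLUSTER_CUTOFF = 10**7
"""Default single-linkage cut distance (bp): 5 kernel widths at scale 2 Mb."""

Locus = tuple[str, str, int]  # (chromosome, arm, position)


@dataclass
class LocusDistanceMatrix:
    """Pairwise genomic distances between co-occurring loci."""

    loci: list[Locus]
    D: np.ndarray = field(repr=False)


def locus_distance_matrix(loci: list[Locus]) -> LocusDistanceMatrix:
    """Same-arm distance = |bp_i - bp_j|; different arms = 1e8 bp."""
    if not loci:
        raise ValueError("empty locus list")
    n = len(loci)
    arms = [(c, a) for c, a, _ in loci]
    pos = np.array([p for _, _, p in loci], dtype=float)
    D = np.full((n, n), float(OFF_ARM_DISTANCE))
    for i in range(n):
        for j in range(n):
            if arms[i] == arms[j]:
                D[i, j] = abs(pos[i] - pos[j])
    return LocusDistanceMatrix(loci=list(loci), D=D)


def cluster_loci(
    dm: LocusDistanceMatrix, cutoff_bp: float = DEFAULT_CLUSTER_CUTOFF
) -> np.ndarray:
    """Single-linkage clusters at linkage distance strictly below the cutoff.

    Returns an integer label per locus; labels are ordered by each cluster's
    leftmost locus (smallest (chromosome, arm, position)), so the assignment
    is deterministic and invariant to input order.
    """
    if cutoff_bp >= OFF_ARM_DISTANCE:
        raise ValueError("cutoff must be below the off-arm distance constant")
    adj = dm.D < cutoff_bp
    _, raw = connected_components(adj, directed=False)
    # relabel by leftmost member locus
    order_key = {}
    for lbl in np.unique(raw):
        members = [dm.loci[i] for i in np.where(raw == lbl)[0]]
        order_key[lbl] = min(members)
    relabel = {
        lbl: new for new, lbl in enumerate(sorted(order_key, key=order_key.get))
    }
    return np.array([relabel[lbl] for lbl in raw], dtype=int)


def build_graph(
    loci: list[Locus], assignment: np.ndarray, cooccurrences: list[Peak]
) -> nx.Graph:
    """Build the co-occurrence graph from a cluster assignment.

    Nodes are clusters (attributes: member loci, spanning interval, best
    source rank); edges carry ``support``, the number of co-occurrences
    linking loci of the two clusters.  Pairs internal to one cluster are
    dropped and counted in ``graph.graph["within_cluster_pairs"]``.
    """
    cluster_of = {locus: int(lbl) for locus, lbl in zip(loci, assignment)}
    G = nx.Graph(within_cluster_pairs=0)
    for lbl in sorted(set(int(x) for x in assignment)):
        members = sorted(l for l, c in cluster_of.items() if c == lbl)
        positions = [p for _, _, p in members]
        G.add_node(
            lbl,
            loci=members,
            interval=(min(positions), max(positions)),
            chromosomes=sorted({c for c, _, _ in members}),
            best_rank=None,
        )
    for pk in cooccurrences:
        for locus in (pk.locus_a, pk.locus_b):
            if locus not in cluster_of:
                raise ValueError(f"co-occurrence locus {locus} has no cluster assignment")
        u = cluster_of[pk.locus_a]
        v = cluster_of[pk.locus_b]
        for node in (u, v):
            br = G.nodes[node]["best_rank"]
            if pk.rank is not None and (br is None or pk.rank < br):
                G.nodes[node]["best_rank"] = pk.rank
        if u == v:
            G.graph["within_cluster_pairs"] += 1
            continue
        if G.has_edge(u, v):
            G[u][v]["support"] += 1
        else:
            G.add_edge(u, v, support=1)
    return G


def prune_core(
    graph: nx.Graph, total_cooccurrences: int, min_fraction: float = 0.05
) -> nx.Graph:
    """Keep edges supported by at least ``min_fraction`` of the co-occurrences.

    "Less than" the threshold is removed, so with 500 co-occurrences at 5% an
    edge of support 25 survives and 24 does not.  Isolated nodes are dropped
    afterward.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must be in (0, 1)")
    threshold = min_fraction * total_cooccurrences
    core = graph.copy()
    weak = [(u, v) for u, v, s in core.edges(data="support") if s < threshold]
    core.remove_edges_from(weak)
    core.remove_nodes_from(list(nx.isolates(core)))
    return core
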