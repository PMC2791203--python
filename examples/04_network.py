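"""Build a co-occurrence network from a ranked peak list.

Clusters the loci of the recovered peak list by genomic distance (single
linkage, 10 Mb cut, off-arm distance 1e8 bp), links clusters whose loci
co-occur, and prunes to the core network of edges supported by at least 5%
of the co-occurrence list.
"""

from cooccur import build_graph, cluster_loci, locus_distance_matrix, prune_core
from cooccur.pipeline import two_lineage_recovery

ranked = two_lineage_recovery(seed=1)["ranked"]
loci = sorted({p.locus_a for p in ranked} | {p.locus_b for p in ranked})

dm = locus_distance_matrix(loci)
assignment = cluster_loci(dm, cutoff_bp=10_000_000)
graph = build_graph(loci, assignment, list(ranked))
core = prune_core(graph, total_cooccurrences=len(ranked), min_fraction=0.05)

print(f"{len(loci)} loci -> {graph.number_of_nodes()} clustered nodes, "
      f"{graph.number_of_edges()} edges")
for u, v, s in sorted(graph.edges(data="support")):
    chrom_u = "/".join(graph.nodes[u]["chromosomes"])
    chrom_v = "/".join(graph.nodes[v]["chromosomes"])
    print(f"  chr{chrom_u} -- chr{chrom_v}  support={s}")
print(f"core network after pruning: {core.number_of_nodes()} nodes, "
      f"{core.number_of_edges()} edges")
print("Each node is a cluster of nearby loci; edge support counts how many")
print("top co-occurrences link the two genomic regions.")
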