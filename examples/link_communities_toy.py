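"""Overlapping link communities on a toy graph.

Builds a bow-tie graph (two triangles sharing one node), clusters its links,
and prints the partition density and the resulting gene modules.  The shared
node ends up in both modules — the overlap that node-partitioning methods
cannot express.
"""

from overlapnet.hlc import LinkGraph, affiliation, cut_at_max_density

graph = LinkGraph(
    [("a", "b"), ("a", "k"), ("b", "k"), ("c", "d"), ("c", "k"), ("d", "k")]
)
partition = cut_at_max_density(graph)
modules = affiliation(graph, partition, min_module_size=3)

print(f"partition density D = {partition.density:.3f} (1.0 = every community a clique)")
for module_id, genes in modules.module_genes.items():
    print(f"{module_id}: {', '.join(genes)}")
print(f"node 'k' belongs to {modules.memberships('k')} -> overlapping membership")
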