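"""Hierarchical link clustering: overlapping community detection on edges.

Instead of partitioning nodes, the algorithm partitions *links*.  Two links
that share a node k, say e_ik and e_jk, are compared through the Jaccard
index of the inclusive neighborhoods of their non-shared endpoints,

    S(e_ik, e_jk) = |eta(i) & eta(j)| / |eta(i) | eta(j)|,

where eta(v) is {v} together with v's neighbors.  Single-linkage
agglomeration over links, with all merges at an equal similarity level
applied simultaneously, yields a link dendrogram.  The dendrogram is cut at
the level maximizing the partition density

    D = (2 / |E|) * sum_c |E_c| * (|E_c| - |V_c| + 1) / ((|V_c| - 1)(|V_c| - 2)),

where the sum runs over link communities c with |E_c| links touching |V_c|
nodes; communities of a single link (|V_c| = 2) contribute zero, since the
formula is undefined there and a lone link carries no density information.
D is 1 when every community induces a clique on at least three nodes and 0
when every community induces a tree.  A node inherits the community of each
of its links, so node communities (the gene modules) may overlap.

Similarities are kept as exact rationals so that "equal level" is exact and
batch merging is independent of link enumeration order; link pairs that
share no node have no defined similarity and never force a merge, so
communities never span graph components.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

Node = Hashable
Link = tuple[Node, Node]


def _canon(u: Node, v: Node) -> Link:
    return (u, v) if repr(u) <= repr(v) else (v, u)


class LinkGraph:
    """Simple undirected graph with stable, canonical link indexing.

    Links are stored sorted lexicographically (by node repr) so that any
    construction order of the same edge set yields identical link indices —
    the basis of the determinism guarantee for everything downstream.
    """

    def __init__(self, edges: Iterable[tuple[Node, Node]]):
        canonical: set[Link] = set()
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop at node {u!r} is not allowed")
            canonical.add(_canon(u, v))
        self.links: list[Link] = sorted(canonical, key=lambda e: (repr(e[0]), repr(e[1])))
        self.link_index: dict[Link, int] = {e: i for i, e in enumerate(self.links)}
        self.neighbors: dict[Node, set[Node]] = defaultdict(set)
        for u, v in self.links:
            self.neighbors[u].add(v)
            self.neighbors[v].add(u)
        self.nodes: list[Node] = sorted(self.neighbors, key=repr)

    @classmethod
    def from_binary_network(cls, net) -> "LinkGraph":
        return cls(net.edges())

    @property
    def n_links(self) -> int:
        return len(self.links)

    def eta(self, v: Node) -> set[Node]:
        """Inclusive neighborhood: the node and its neighbors."""
        if v not in self.neighbors:
            raise KeyError(f"node {v!r} not in graph")
        return {v} | self.neighbors[v]


def link_similarity(g: LinkGraph, e_a: Link, e_b: Link) -> Fraction:
    """Jaccard similarity of two links that share exactly one node."""
    a, b = set(e_a), set(e_b)
    shared = a & b
    if len(shared) != 1:
        raise ValueError(
            f"links {e_a} and {e_b} share {len(shared)} nodes; similarity is "
            "defined only for links sharing exactly one node"
        )
    (i,) = a - shared
    (j,) = b - shared
    eta_i, eta_j = g.eta(i), g.eta(j)
    return Fraction(len(eta_i & eta_j), len(eta_i | eta_j))


@dataclass(frozen=True)
class LinkDendrogram:
    """Single-linkage merge history over links.

    ``levels`` lists, in descending similarity order, each distinct level and
    the link-index pairs that attain it; replaying the pairs through a
    union-find reproduces the partition sequence.
    """

    n_links: int
    levels: list[tuple[Fraction, list[tuple[int, int]]]]

    def __post_init__(self) -> None:
        sims = [lvl for lvl, _ in self.levels]
        if any(s2 > s1 for s1, s2 in zip(sims, sims[1:])):
            raise ValueError("dendrogram levels must be non-increasing")


def _pair_similarities(g: LinkGraph) -> dict[Fraction, list[tuple[int, int]]]:
    by_level: dict[Fraction, list[tuple[int, int]]] = defaultdict(list)
    for k in g.nodes:
        incident = sorted(
            (g.link_index[_canon(k, nb)] for nb in g.neighbors[k])
        )
        for x in range(len(incident)):
            for y in range(x + 1, len(incident)):
                ia, ib = incident[x], incident[y]
                sim = link_similarity(g, g.links[ia], g.links[ib])
                by_level[sim].append((ia, ib))
    return by_level


def build_link_dendrogram(g: LinkGraph) -> LinkDendrogram:
    """Single-linkage agglomeration of links, batching equal-similarity merges."""
    if g.n_links < 1:
        raise ValueError("graph has no links")
    by_level = _pair_similarities(g)
    levels = [
        (sim, sorted(by_level[sim])) for sim in sorted(by_level, reverse=True)
    ]
    return LinkDendrogram(n_links=g.n_links, levels=levels)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        return True


@dataclass(frozen=True)
class LinkPartition:
    """Assignment of every link to one community, with density bookkeeping."""

    graph: LinkGraph
    labels: list[int]  # community label per link index
    density: float
    level: Fraction | None  # similarity level of the cut (None = leaf partition)

    def communities(self) -> dict[int, list[Link]]:
        out: dict[int, list[Link]] = defaultdict(list)
        for idx, lab in enumerate(self.labels):
            out[lab].append(self.graph.links[idx])
        return dict(out)

    def community_stats(self) -> list[tuple[int, int]]:
        """(link count, node count) per community."""
        stats = []
        for links in self.communities().values():
            nodes = {n for e in links for n in e}
            stats.append((len(links), len(nodes)))
        return stats


def _community_term(m_c: int, n_c: int) -> float:
    if n_c <= 2:
        return 0.0
    return m_c * (m_c - n_c + 1) / ((n_c - 1) * (n_c - 2))


def partition_density(g: LinkGraph, labels: Sequence[int] | Mapping[Link, int]) -> float:
    """Partition density D of a link partition.

    ``labels`` is either one community label per canonical link index or a
    mapping from link to label covering every link exactly once.
    """
    if isinstance(labels, Mapping):
        lab_list = []
        for e in g.links:
            key = e if e in labels else (e[1], e[0])
            if key not in labels:
                raise ValueError(f"partition does not cover link {e}")
            lab_list.append(labels[key])
        labels = lab_list
    if len(labels) != g.n_links:
        raise ValueError(
            f"partition covers {len(labels)} links but the graph has {g.n_links}"
        )
    if g.n_links == 0:
        return 0.0
    members: dict[int, list[Link]] = defaultdict(list)
    for idx, lab in enumerate(labels):
        members[lab].append(g.links[idx])
    total = 0.0
    for links in members.values():
        nodes = {n for e in links for n in e}
        total += _community_term(len(links), len(nodes))
    return 2.0 * total / g.n_links


def cut_at_max_density(g: LinkGraph, dendro: LinkDendrogram | None = None) -> LinkPartition:
    """Partition at the dendrogram level maximizing partition density.

    Evaluates D at the all-singletons leaf partition and after each distinct
    merge level; ties go to the higher-similarity (finer) partition.  The
    density is maintained incrementally: merging two link clusters replaces
    their two community terms with the term of the union.
    """
    if dendro is None:
        dendro = build_link_dendrogram(g)
    n = g.n_links
    uf = _UnionFind(n)
    link_count = [1] * n
    node_sets: list[set[Node] | None] = [set(e) for e in g.links]
    terms = [0.0] * n  # every singleton link community contributes 0
    total = 0.0

    best_density = 2.0 * total / n  # leaf partition
    best_level_idx = -1  # -1 = leaf partition

    for lvl_idx, (_sim, pairs) in enumerate(dendro.levels):
        for a, b in pairs:
            ra, rb = uf.find(a), uf.find(b)
            if ra == rb:
                continue
            total -= terms[ra] + terms[rb]
            sa, sb = node_sets[ra], node_sets[rb]
            assert sa is not None and sb is not None
            if len(sa) < len(sb):
                ra_small, ra_big = ra, rb
            else:
                ra_small, ra_big = rb, ra
            node_sets[ra_big].update(node_sets[ra_small])  # type: ignore[union-attr]
            node_sets[ra_small] = None
            merged_links = link_count[ra] + link_count[rb]
            uf.union(ra, rb)
            root = uf.find(ra)
            if root != ra_big:  # keep bookkeeping on the union-find root
                node_sets[root] = node_sets[ra_big]
                if root != ra_big:
                    node_sets[ra_big] = None
            link_count[root] = merged_links
            new_term = _community_term(merged_links, len(node_sets[root]))  # type: ignore[arg-type]
            terms[ra] = terms[rb] = 0.0
            terms[root] = new_term
            total += new_term
        density = 2.0 * total / n
        if density > best_density:
            best_density = density
            best_level_idx = lvl_idx

    # replay to the best level to extract the partition labels
    uf = _UnionFind(n)
    for lvl_idx in range(best_level_idx + 1):
        for a, b in dendro.levels[lvl_idx][1]:
            uf.union(a, b)
    roots = [uf.find(i) for i in range(n)]
    relabel = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    labels = [relabel[r] for r in roots]
    level = None if best_level_idx < 0 else dendro.levels[best_level_idx][0]
    return LinkPartition(graph=g, labels=labels, density=best_density, level=level)


@dataclass(frozen=True)
class AffiliationMatrix:
    """Binary gene × module membership allowing overlap.

    ``module_genes`` maps module id to its (sorted) member genes; modules are
    canonically ordered by their sorted gene tuple so identical networks give
    identical module ids regardless of node enumeration order.
    """

    gene_ids: list[str]
    module_ids: list[str]
    values: np.ndarray  # 0/1, genes × modules
    module_genes: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return len(self.module_ids)

    def memberships(self, gene: str) -> list[str]:
        i = self.gene_ids.index(gene)
        return [m for m, f in zip(self.module_ids, self.values[i]) if f]

    def affiliated_genes(self) -> list[str]:
        mask = np.asarray(self.values).sum(axis=1) > 0
        return [g for g, keep in zip(self.gene_ids, mask) if keep]


def affiliation(
    g: LinkGraph, partition: LinkPartition, min_module_size: int = 3
) -> AffiliationMatrix:
    """Gene modules from a link partition: a gene joins every community that
    contains one of its links; communities with fewer than ``min_module_size``
    genes are dropped (their genes may end up module-less)."""
    communities = partition.communities()
    gene_sets = []
    for links in communities.values():
        genes = sorted({str(n) for e in links for n in e})
        if len(genes) >= min_module_size:
            gene_sets.append(genes)
    gene_sets.sort(key=tuple)
    module_ids = [f"M{k + 1}" for k in range(len(gene_sets))]
    gene_ids = sorted({str(n) for n in g.nodes})
    values = np.zeros((len(gene_ids), len(gene_sets)), dtype=np.int8)
    pos = {gid: i for i, gid in enumerate(gene_ids)}
    for k, genes in enumerate(gene_sets):
        for gid in genes:
            values[pos[gid], k] = 1
    return AffiliationMatrix(
        gene_ids=gene_ids,
        module_ids=module_ids,
        values=values,
        module_genes=dict(zip(module_ids, gene_sets)),
    )


@dataclass(frozen=True)
class OverlapHistogram:
    counts: dict[str, int]  # module count per affiliated gene
    fraction_single: float
    fraction_multi: float


def overlap_histogram(f: AffiliationMatrix) -> OverlapHistogram:
    """Module-membership counts of affiliated genes and the overlap fraction."""
    per_gene = np.asarray(f.values).sum(axis=1)
    affiliated = per_gene > 0
    if not affiliated.any():
        return OverlapHistogram(counts={}, fraction_single=0.0, fraction_multi=0.0)
    counts = {
        g: int(c) for g, c in zip(f.gene_ids, per_gene) if c > 0
    }
    n_aff = int(affiliated.sum())
    multi = int((per_gene > 1).sum())
    return OverlapHistogram(
        counts=counts,
        fraction_single=(n_aff - multi) / n_aff,
        fraction_multi=multi / n_aff,
    )
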