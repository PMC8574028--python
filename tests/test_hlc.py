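"""Hierarchical link clustering: similarity, dendrogram, density, modules.

The key correctness check is an oracle equivalence: on an enumerated suite
of small graphs, the incremental partition-density optimizer must agree
exactly with a naive O(L^3) single-linkage implementation that recomputes
the density from scratch at every level.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from overlapnet.hlc import (
    LinkGraph,
    affiliation,
    build_link_dendrogram,
    cut_at_max_density,
    link_similarity,
    overlap_histogram,
    partition_density,
)


# ---------------------------------------------------------------------------
# independent naive oracle


def naive_density(links, labels) -> float:
    """Partition density evaluated directly from its definition."""
    if not links:
        return 0.0
    groups = {}
    for link, lab in zip(links, labels):
        groups.setdefault(lab, []).append(link)
    total = 0.0
    for group in groups.values():
        m_c = len(group)
        nodes = {n for e in group for n in e}
        n_c = len(nodes)
        if n_c > 2:
            total += m_c * (m_c - n_c + 1) / ((n_c - 1) * (n_c - 2))
    return 2.0 * total / len(links)


def naive_best_cut_density(graph: LinkGraph) -> float:
    """O(L^3) single-linkage over links; returns the best density over all
    levels (including the all-singletons leaf partition)."""
    links = graph.links
    n = len(links)
    sims = {}
    for a, b in combinations(range(n), 2):
        shared = set(links[a]) & set(links[b])
        if len(shared) == 1:
            sims[(a, b)] = link_similarity(graph, links[a], links[b])
    clusters = [{i} for i in range(n)]
    labels = list(range(n))
    best = naive_density(links, labels)
    remaining = dict(sims)
    while remaining:
        level = max(remaining.values())
        # merge every cluster pair connected at this level, transitively
        at_level = [pair for pair, s in remaining.items() if s == level]
        for a, b in at_level:
            la, lb = labels[a], labels[b]
            if la != lb:
                labels = [la if l == lb else l for l in labels]
        remaining = {
            (a, b): s for (a, b), s in remaining.items() if labels[a] != labels[b]
        }
        best = max(best, naive_density(links, labels))
    return best


# ---------------------------------------------------------------------------


class TestLinkSimilarity:
    def test_bare_path_is_one_third(self):
        g = LinkGraph([("a", "k"), ("k", "b")])
        assert link_similarity(g, ("a", "k"), ("k", "b")) == Fraction(1, 3)

    def test_triangle_links_fully_similar(self, triangle):
        assert link_similarity(triangle, ("a", "c"), ("b", "c")) == 1

    def test_disjoint_links_rejected(self):
        g = LinkGraph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="share"):
            link_similarity(g, ("a", "b"), ("c", "d"))

    def test_range_and_equality_condition(self):
        """Similarity lies in [0,1]; equals 1 iff the inclusive neighborhoods
        of the non-shared endpoints coincide."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 9)
            edges = [
                (int(i), int(j))
                for i, j in combinations(range(n), 2)
                if rng.random() < 0.5
            ]
            if not edges:
                continue
            g = LinkGraph(edges)
            for e1, e2 in combinations(g.links, 2):
                shared = set(e1) & set(e2)
                if len(shared) != 1:
                    continue
                s = link_similarity(g, e1, e2)
                assert 0 <= s <= 1
                (i,) = set(e1) - shared
                (j,) = set(e2) - shared
                assert (s == 1) == (g.eta(i) == g.eta(j))


class TestPartitionDensity:
    def test_two_disjoint_triangle_cliques_give_one(self, two_triangles):
        labels = [0 if set(e) <= {"a", "b", "c"} else 1 for e in two_triangles.links]
        assert partition_density(two_triangles, labels) == pytest.approx(1.0)

    def test_tree_community_gives_zero(self, star3):
        assert partition_density(star3, [0, 0, 0]) == pytest.approx(0.0)

    def test_two_disconnected_edges_give_minus_one_third(self):
        g = LinkGraph([("a", "b"), ("c", "d")])
        assert partition_density(g, [0, 0]) == pytest.approx(-1 / 3)

    def test_partition_must_cover_links(self, triangle):
        with pytest.raises(ValueError, match="covers"):
            partition_density(triangle, [0, 0])

    def test_clique_communities_of_three_plus_nodes_give_one(self):
        """If every community induces a clique on >= 3 nodes, D = 1."""
        for k in (3, 4, 5):
            clique = LinkGraph(list(combinations(range(k), 2)))
            assert partition_density(clique, [0] * clique.n_links) == pytest.approx(1.0)


class TestDendrogramAndCut:
    def test_single_triangle_merges_at_one(self, triangle):
        dendro = build_link_dendrogram(triangle)
        assert dendro.levels[0][0] == 1
        part = cut_at_max_density(triangle, dendro)
        assert part.density == pytest.approx(1.0)
        assert len(set(part.labels)) == 1

    def test_bowtie_splits_into_two_triangles(self, bowtie):
        part = cut_at_max_density(bowtie)
        assert part.density == pytest.approx(1.0)
        communities = [set(n for e in links for n in e) for links in part.communities().values()]
        assert sorted(sorted(c) for c in communities) == [["a", "b", "k"], ["c", "d", "k"]]

    def test_disconnected_components_never_merge(self, two_triangles):
        part = cut_at_max_density(two_triangles)
        for links in part.communities().values():
            nodes = {n for e in links for n in e}
            assert nodes <= {"a", "b", "c"} or nodes <= {"x", "y", "z"}

    def test_path_of_three_ties_resolve_to_finer_partition(self):
        g = LinkGraph([("a", "b"), ("b", "c")])
        part = cut_at_max_density(g)
        assert part.density == pytest.approx(0.0)
        assert len(set(part.labels)) == 2  # finer of the two D=0 partitions

    def test_two_triangles_with_bridge_merge_triangles_first(self):
        g = LinkGraph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("c", "x"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        dendro = build_link_dendrogram(g)
        # the triangles' internal links merge at similarity 1 before any
        # merge involving the bridge
        first_level, pairs = dendro.levels[0]
        assert first_level == 1
        bridge_idx = g.link_index[("c", "x")]
        assert all(bridge_idx not in p for p in pairs)

    @pytest.mark.parametrize(
        "edges",
        [
            [("a", "b"), ("b", "c")],
            [("a", "b"), ("b", "c"), ("a", "c")],
            [(0, 1), (1, 2), (2, 3), (3, 4)],  # path
            [(0, 1), (1, 2), (2, 3), (3, 0)],  # 4-cycle
            list(combinations(range(4), 2)),  # K4
            list(combinations(range(5), 2)),  # K5 (10 links)
            [("a", "b"), ("a", "k"), ("b", "k"), ("c", "d"), ("c", "k"), ("d", "k")],  # bow-tie
            # barbell: two triangles joined by a path
            [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (4, 5), (5, 6), (4, 6)],
            [("h", x) for x in "abcde"],  # 5-star
        ],
    )
    def test_oracle_equivalence_enumerated_graphs(self, edges):
        g = LinkGraph(edges)
        part = cut_at_max_density(g)
        assert part.density == pytest.approx(naive_best_cut_density(g), abs=1e-12)
        # returned labels really partition the links and reproduce D
        assert len(part.labels) == g.n_links
        assert naive_density(g.links, part.labels) == pytest.approx(part.density)

    def test_oracle_equivalence_random_graphs(self):
        rng = np.random.default_rng(12)
        checked = 0
        while checked < 12:
            n = int(rng.integers(4, 8))
            edges = [
                (int(i), int(j))
                for i, j in combinations(range(n), 2)
                if rng.random() < 0.45
            ]
            if not 1 <= len(edges) <= 12:
                continue
            g = LinkGraph(edges)
            part = cut_at_max_density(g)
            assert part.density == pytest.approx(naive_best_cut_density(g), abs=1e-12)
            checked += 1

    def test_determinism_under_node_relabeling(self, bowtie):
        relabeled = LinkGraph(
            [("z9", "z8"), ("z9", "m"), ("z8", "m"), ("q", "p"), ("q", "m"), ("p", "m")]
        )
        p1 = cut_at_max_density(bowtie)
        p2 = cut_at_max_density(relabeled)
        assert p1.density == pytest.approx(p2.density)
        sizes1 = sorted((len(v), len({n for e in v for n in e})) for v in p1.communities().values())
        sizes2 = sorted((len(v), len({n for e in v for n in e})) for v in p2.communities().values())
        assert sizes1 == sizes2


class TestAffiliation:
    def test_bowtie_shared_node_in_two_modules(self, bowtie):
        part = cut_at_max_density(bowtie)
        f = affiliation(bowtie, part, min_module_size=3)
        assert f.n_modules == 2
        assert f.memberships("k") == ["M1", "M2"]
        for gene in "abcd":
            assert len(f.memberships(gene)) == 1

    def test_small_modules_dropped(self):
        g = LinkGraph([("a", "b"), ("c", "d"), ("d", "e"), ("c", "e")])
        part = cut_at_max_density(g)
        f = affiliation(g, part, min_module_size=3)
        # the lone a-b link forms a 2-gene community -> dropped
        assert f.n_modules == 1
        assert f.module_genes["M1"] == ["c", "d", "e"]
        assert f.memberships("a") == []

    def test_overlap_histogram_bowtie(self, bowtie):
        part = cut_at_max_density(bowtie)
        f = affiliation(bowtie, part, min_module_size=3)
        hist = overlap_histogram(f)
        assert hist.fraction_multi == pytest.approx(1 / 5)
        assert hist.counts["k"] == 2

    def test_overlap_histogram_disjoint_modules(self, two_triangles):
        part = cut_at_max_density(two_triangles)
        f = affiliation(two_triangles, part, min_module_size=3)
        hist = overlap_histogram(f)
        assert hist.fraction_multi == 0.0
        assert hist.fraction_single == 1.0

    def test_node_memberships_union_of_link_memberships(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(5, 10))
            edges = [
                (int(i), int(j))
                for i, j in combinations(range(n), 2)
                if rng.random() < 0.4
            ]
            if not edges:
                continue
            g = LinkGraph(edges)
            part = cut_at_max_density(g)
            f = affiliation(g, part, min_module_size=2)
            communities = part.communities()
            by_genes = {}
            for lab, links in communities.items():
                genes = sorted(str(x) for e in links for x in e)
                if len(set(genes)) >= 2:
                    by_genes.setdefault(tuple(sorted(set(genes))), 0)
            for genes_tuple in by_genes:
                assert list(genes_tuple) in list(f.module_genes.values())
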