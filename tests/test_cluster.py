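"""The hybrid clustering: largest component, Jarvis-Patrick reweighting,
average-linkage agglomeration, cluster-count estimation, and bootstrap
stability -- each checked against brute-force references."""

import pytest

from hicdecon.cluster import (ClusterParams, _agglomerate_engine, agglomerate,
                              bootstrap_stability, estimate_n_clusters,
                              jarvis_patrick, largest_component)
from hicdecon.errors import DataError
from hicdecon.simulate import pairs_from_graph, simulate_planted_graph

from conftest import make_contig, make_graph, random_weighted_graph
from oracles import brute_agglomerate, brute_components, brute_jp


class TestLargestComponent:
    def test_single_component_is_identity(self):
        cg = make_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        comp, discarded = largest_component(cg)
        assert set(comp.graph.nodes) == {"a", "b", "c"} and discarded == frozenset()

    def test_larger_component_kept(self):
        cg = make_graph([("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "e", 1),
                         ("x", "y", 1), ("y", "z", 1)])
        comp, discarded = largest_component(cg)
        assert set(comp.graph.nodes) == {"a", "b", "c", "d", "e"}
        assert discarded == frozenset({"x", "y", "z"})

    def test_size_tie_broken_by_total_length(self):
        cg = make_graph([("a", "b", 1), ("x", "y", 1)],
                        lengths={"a": 100, "b": 100, "x": 5000, "y": 5000})
        comp, _ = largest_component(cg)
        assert set(comp.graph.nodes) == {"x", "y"}

    def test_full_tie_broken_by_smallest_id(self):
        cg = make_graph([("a", "b", 1), ("x", "y", 1)])
        comp, _ = largest_component(cg)
        assert set(comp.graph.nodes) == {"a", "b"}

    def test_empty_graph_is_error(self):
        cg = make_graph([("a", "b", 1)]).subgraph([])
        with pytest.raises(DataError):
            largest_component(cg)

    def test_matches_flood_fill_on_random_graphs(self, rng):
        for _ in range(20):
            cg = random_weighted_graph(rng, max_nodes=20)
            comp, discarded = largest_component(cg)
            comps = brute_components(cg.graph)
            best = max(len(c) for c in comps)
            assert len(comp.graph.nodes) == best
            assert set(comp.graph.nodes) in [c for c in comps if len(c) == best]


class TestJarvisPatrick:
    def test_clique_shared_neighbors(self):
        edges = [(a, b, 1.0) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        cg = make_graph(edges)
        jp = jarvis_patrick(cg, ClusterParams(k=3))
        for u, v in jp.graph.edges:
            assert jp.graph[u][v]["shared"] == 2
            assert jp.graph[u][v]["weight"] == pytest.approx(2 / 3)

    def test_bridge_between_triangles_removed(self):
        edges = [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
                 ("d", "e", 1), ("e", "f", 1), ("d", "f", 1),
                 ("a", "d", 1)]
        jp = jarvis_patrick(make_graph(edges), ClusterParams(k=2))
        # bridge endpoints share no nearest neighbors -> bridge removed
        assert not jp.graph.has_edge("a", "d")
        # the untouched triangle survives intact
        assert all(jp.graph.has_edge(u, v) for u, v in [("a", "b"), ("a", "c"), ("b", "c")])
        # d's k=2 list is skewed by the bridge (ties break by id), so (d,e)
        # also loses its shared neighbors while (d,f) and (e,f) survive
        assert jp.graph.has_edge("d", "f") and jp.graph.has_edge("e", "f")

    def test_star_graph_fully_disconnects(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        jp = jarvis_patrick(make_graph(edges), ClusterParams(k=5))
        assert jp.n_edges == 0
        assert jp.n_nodes == 6  # isolated nodes stay, reported unclustered later

    def test_count_mode_keeps_raw_shared(self):
        edges = [(a, b, 1.0) for i, a in enumerate("abcd") for b in "abcd"[i + 1:]]
        jp = jarvis_patrick(make_graph(edges), ClusterParams(k=3, jp_weight_mode="count"))
        for u, v in jp.graph.edges:
            assert jp.graph[u][v]["weight"] == 2.0

    def test_invalid_k_is_error(self):
        with pytest.raises(ValueError):
            ClusterParams(k=0)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(40):
            cg = random_weighted_graph(rng, max_nodes=25)
            k = int(rng.integers(1, 12))
            jp = jarvis_patrick(cg, ClusterParams(k=k))
            expected = brute_jp(cg.graph, k)
            got = {frozenset((u, v)): (d["shared"], d["weight"])
                   for u, v, d in jp.graph.edges(data=True)}
            assert set(got) == set(expected)
            for key in expected:
                assert got[key][0] == expected[key][0]
                assert got[key][1] == pytest.approx(expected[key][1])


class TestAgglomerate:
    def test_two_cliques_with_weak_bridge(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0),
                 ("d", "e", 1.0), ("e", "f", 1.0), ("d", "f", 1.0),
                 ("c", "d", 0.1)]
        result = agglomerate(make_graph(edges), n_clusters=2)
        parts = {frozenset(m) for m in result.clusters.values()}
        assert parts == {frozenset("abc"), frozenset("def")}

    def test_n_clusters_equals_nodes_no_merges(self):
        cg = make_graph([("a", "b", 1.0), ("b", "c", 0.5)])
        result = agglomerate(cg, n_clusters=3)
        assert len(result.clusters) == 3
        assert result.merge_trace == []

    def test_n_clusters_exceeding_nodes_is_error(self):
        cg = make_graph([("a", "b", 1.0)])
        with pytest.raises(DataError):
            agglomerate(cg, n_clusters=5)

    def test_isolated_nodes_unclustered(self):
        cg = make_graph([("a", "b", 1.0)])
        cg.graph.add_node("z", length=10, site_count=1)
        result = agglomerate(cg, n_clusters=1)
        assert result.unclustered == frozenset({"z"})
        assert result.unclustered_reasons["z"] == "jp_isolated"

    def test_partition_property(self, rng):
        for _ in range(10):
            cg = random_weighted_graph(rng, max_nodes=15)
            n = int(rng.integers(1, cg.n_nodes + 1))
            result = agglomerate(cg, n)
            result.validate(universe=list(cg.graph.nodes))

    def test_merge_sequence_matches_brute_force(self, rng):
        for _ in range(30):
            cg = random_weighted_graph(rng, max_nodes=10)
            n = int(rng.integers(1, 4))
            result = agglomerate(cg, n)
            b_clusters, b_trace = brute_agglomerate(cg.graph, n)
            assert [(s, p) for s, p, _ in result.merge_trace] == \
                   [(s, p) for s, p, _ in b_trace]
            for (_, _, l1), (_, _, l2) in zip(result.merge_trace, b_trace):
                assert l1 == pytest.approx(l2)
            assert {frozenset(m) for m in result.clusters.values()} == \
                   {frozenset(m) for m in b_clusters.values()}


class TestEstimateNClusters:
    def test_planted_three_blocks(self):
        cg, _ = simulate_planted_graph(3, 12, seed=5)
        pred, curve = estimate_n_clusters(cg, 2, 10)
        assert pred == 3

    def test_single_clique_enrichment_reaches_one(self):
        edges = [(a, b, 1.0, 3) for i, a in enumerate("abcdef") for b in "abcdef"[i + 1:]]
        cg = make_graph(edges)
        _, _, _, states = _agglomerate_engine(cg, stop_n=1)
        assert states[-1][0] == 1
        assert states[-1][1] == pytest.approx(1.0)

    def test_curve_monotone_as_clusters_merge(self, rng):
        for _ in range(10):
            cg = random_weighted_graph(rng, max_nodes=20)
            _, _, _, states = _agglomerate_engine(cg, stop_n=1)
            es = [e for _, e in states]
            assert all(b >= a - 1e-12 for a, b in zip(es, es[1:]))

    def test_invalid_range_is_error(self):
        cg, _ = simulate_planted_graph(3, 5, seed=1)
        with pytest.raises(DataError):
            estimate_n_clusters(cg, 10, 5)


class TestAbundanceRobustness:
    def test_scaling_one_species_leaves_assignment_unchanged(self):
        # Jarvis-Patrick neighborhoods depend only on weight ranks, which a
        # per-species scale factor cannot change on separable data.
        cg, labels = simulate_planted_graph(4, 12, seed=9)
        boosted = cg.subgraph(cg.graph.nodes)
        sp0 = {v for v, s in labels.items() if s == "sp00"}
        for u, v, d in boosted.graph.edges(data=True):
            if u in sp0 or v in sp0:
                d["weight"] *= 10
                d["raw_links"] *= 10

        def cluster(graph):
            comp, _ = largest_component(graph)
            jp = jarvis_patrick(comp, ClusterParams(k=12))
            return {frozenset(m) for m in agglomerate(jp, 4).clusters.values()}

        base = cluster(cg)
        assert base == cluster(boosted)
        assert base == {frozenset(v for v in labels if labels[v] == f"sp{s:02d}")
                        for s in range(4)}


@pytest.fixture(scope="module")
def planted_pairs():
    cg, labels = simulate_planted_graph(3, 12, seed=21)
    contigs = [make_contig(v, length=10_000, sites=(0,)) for v in sorted(cg.graph.nodes)]
    return pairs_from_graph(cg), contigs, labels


class TestBootstrapStability:
    def test_separable_structure_is_stable(self, planted_pairs):
        pairs, contigs, labels = planted_pairs
        res = bootstrap_stability(pairs, contigs, ClusterParams(k=12), n_clusters=3,
                                  B=5, seed=3)
        assert res.mean_stability >= 0.99
        assert all(a == pytest.approx(1.0) for a in res.ari)

    def test_identical_seed_reproduces_identical_output(self, planted_pairs):
        pairs, contigs, _ = planted_pairs
        a = bootstrap_stability(pairs, contigs, ClusterParams(k=12), 3, B=2, seed=7)
        b = bootstrap_stability(pairs, contigs, ClusterParams(k=12), 3, B=2, seed=7)
        assert a.stability == b.stability
        assert a.ari == b.ari

    def test_invalid_replicate_count_is_error(self, planted_pairs):
        pairs, contigs, _ = planted_pairs
        with pytest.raises(ValueError):
            bootstrap_stability(pairs, contigs, ClusterParams(), 3, B=0, seed=1)
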