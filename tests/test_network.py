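"""Network construction, batching, motif weights and clustering.

Brute-force oracles: triangle enumeration over node triples, direct
Newman-modularity arithmetic, and exhaustive search over all set
partitions of small graphs.
"""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ctxgsa import (
    GeneSet,
    Network,
    build_graph,
    edmot_partition,
    fetch_string_edges,
    modularity,
    motif_weights,
    plan_batches,
)
from ctxgsa.network import Clustering, edge_enhanced_graph

from conftest import edge_frame


# ---------------------------------------------------------------------------
# oracles


def brute_triangle_weights(g: nx.Graph) -> dict:
    """Count triangles per edge by enumerating all node triples."""
    counts = {tuple(sorted(e)): 0 for e in g.edges}
    for a, b, c in itertools.combinations(sorted(g.nodes), 3):
        if g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c):
            for e in [(a, b), (b, c), (a, c)]:
                counts[tuple(sorted(e))] += 1
    return counts


def newman_modularity(g: nx.Graph, communities) -> float:
    """Q = sum_i (e_ii - a_i^2) computed directly from edge counts."""
    m = g.number_of_edges()
    q = 0.0
    for comm in communities:
        internal = sum(1 for u, v in g.edges if u in comm and v in comm)
        degree = sum(g.degree(n) for n in comm)
        q += internal / m - (degree / (2 * m)) ** 2
    return q


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


# ---------------------------------------------------------------------------
# build_graph


class TestBuildGraph:
    def test_confidence_threshold_strict(self, gene_set_factory):
        gs = gene_set_factory(["A", "B", "C"])
        net = build_graph(gs, edge_frame([("A", "B", 0.9), ("B", "C", 0.04)]))
        assert net.n_edges == 1
        assert net.graph.has_edge("A", "B")

    def test_at_threshold_removed(self, gene_set_factory):
        gs = gene_set_factory(["A", "B"])
        net = build_graph(gs, edge_frame([("A", "B", 0.05)]))
        assert net.n_edges == 0

    def test_self_loop_dropped(self, gene_set_factory):
        net = build_graph(gene_set_factory(["A", "B"]), edge_frame([("A", "A", 0.9)]))
        assert net.n_edges == 0

    def test_duplicate_rows_keep_max(self, gene_set_factory):
        net = build_graph(
            gene_set_factory(["A", "B"]),
            edge_frame([("A", "B", 0.3), ("B", "A", 0.7)]),
        )
        assert net.graph["A"]["B"]["confidence"] == pytest.approx(0.7)

    def test_string_thousand_scale_normalized(self, gene_set_factory):
        net = build_graph(gene_set_factory(["A", "B"]), edge_frame([("A", "B", 700)]))
        assert net.graph["A"]["B"]["confidence"] == pytest.approx(0.7)

    def test_edges_outside_gene_set_excluded(self, gene_set_factory):
        net = build_graph(gene_set_factory(["A", "B"]), edge_frame([("A", "Z", 0.9)]))
        assert net.n_edges == 0

    def test_empty_edge_table_gives_isolated_nodes(self, gene_set_factory):
        net = build_graph(gene_set_factory(["A", "B"]), edge_frame([]))
        assert len(net) == 2 and net.n_edges == 0


# ---------------------------------------------------------------------------
# batching


class TestPlanBatches:
    def test_single_window_at_or_below_api_limit(self):
        assert plan_batches(1500).windows == [(0, 1500)]
        assert plan_batches(2000).windows == [(0, 2000)]

    def test_stride_arithmetic(self):
        # covering-index enumeration: stride 800, clipped final window
        assert plan_batches(2500).windows == [(0, 1000), (800, 1800), (1600, 2500)]

    def test_windows_cover_all_indices_with_exact_overlap(self):
        for n in [2001, 2500, 3700, 5000]:
            plan = plan_batches(n)
            covered = set()
            for start, end in plan:
                covered |= set(range(start, end))
            assert covered == set(range(n))
            for (s1, e1), (s2, e2) in zip(plan.windows, plan.windows[1:]):
                if e2 - s2 == 1000:  # full windows overlap by exactly 200
                    assert e1 - s2 == 200

    def test_invalid_parameter_ordering(self):
        with pytest.raises(ValueError):
            plan_batches(10, batch_size=100, overlap=100)
        with pytest.raises(ValueError):
            plan_batches(10, batch_size=3000, overlap=200, api_limit=2000)


class _FixtureAdapter:
    def __init__(self, responses):
        self.responses = list(responses)
        self.calls = 0

    def fetch(self, genes):
        frame = self.responses[self.calls]
        self.calls += 1
        return frame


class TestFetchEdges:
    def test_disjoint_windows_union(self, gene_set_factory):
        gs = gene_set_factory([f"G{i}" for i in range(6)])
        plan = plan_batches(6, batch_size=3, overlap=1, api_limit=4)
        adapter = _FixtureAdapter(
            [
                edge_frame([("G0", "G1", 0.5)]),
                edge_frame([("G2", "G3", 0.6)]),
                edge_frame([("G4", "G5", 0.7)]),
            ]
        )
        edges = fetch_string_edges(gs, plan, adapter)
        assert len(edges) == 3

    def test_overlapping_duplicate_keeps_max(self, gene_set_factory):
        gs = gene_set_factory([f"G{i}" for i in range(6)])
        plan = plan_batches(6, batch_size=4, overlap=2, api_limit=5)
        adapter = _FixtureAdapter(
            [edge_frame([("G1", "G2", 0.3)]), edge_frame([("G2", "G1", 0.8)])]
        )
        edges = fetch_string_edges(gs, plan, adapter)
        assert len(edges) == 1
        assert edges["combined_score"].iloc[0] == pytest.approx(0.8)

    def test_all_empty_responses_warn_empty(self, gene_set_factory):
        gs = gene_set_factory(["A", "B"])
        adapter = _FixtureAdapter([edge_frame([])])
        edges = fetch_string_edges(gs, plan_batches(2), adapter)
        assert edges.empty


# ---------------------------------------------------------------------------
# motif weights


class TestMotifWeights:
    def test_triangle_every_edge_one(self):
        g = nx.complete_graph(["A", "B", "C"])
        assert set(motif_weights(Network(graph=g)).values()) == {1}

    def test_k4_every_edge_two(self):
        # each K4 edge lies in exactly 2 of the 4 triangles
        g = nx.complete_graph(["A", "B", "C", "D"])
        w = motif_weights(Network(graph=g))
        assert len(w) == 6 and set(w.values()) == {2}

    def test_path_has_no_triangles(self):
        g = nx.path_graph(["A", "B", "C"])
        assert set(motif_weights(Network(graph=g)).values()) == {0}

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(rng.integers(5, 31), 0.3, seed=int(seed))
        g = nx.relabel_nodes(g, {n: f"N{n:02d}" for n in g.nodes})
        assert motif_weights(Network(graph=g)) == brute_triangle_weights(g)


# ---------------------------------------------------------------------------
# modularity


class TestModularity:
    def test_two_disconnected_triangles(self):
        # closed form: e_ii = 1/2 each, a_i = 1/2 each -> Q = 2*(1/2 - 1/4)
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes})
        cl = Clustering(
            clusters=[{"N0", "N1", "N2"}, {"N3", "N4", "N5"}], dropped=set(), params={}
        )
        assert modularity(Network(graph=g), cl) == pytest.approx(0.5)

    def test_single_cluster_matches_direct_formula(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(8, 0.5, seed=1), {n: f"N{n}" for n in range(8)})
        cl = Clustering(clusters=[set(g.nodes)], dropped=set(), params={})
        assert modularity(Network(graph=g), cl) == pytest.approx(
            newman_modularity(g, [set(g.nodes)])
        )
        assert modularity(Network(graph=g), cl) <= 0 + 1e-12

    def test_empty_edge_set_defined_zero(self):
        g = nx.empty_graph(3)
        g = nx.relabel_nodes(g, {n: f"N{n}" for n in g.nodes})
        cl = Clustering(clusters=[], dropped=set(g.nodes), params={})
        assert modularity(Network(graph=g), cl) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_random_partition_never_beats_exhaustive_best(self, seed):
        g = nx.relabel_nodes(
            nx.gnp_random_graph(7, 0.45, seed=int(seed)), {n: f"N{n}" for n in range(7)}
        )
        if g.number_of_edges() == 0:
            pytest.skip("edgeless draw")
        best = max(
            newman_modularity(g, [set(p) for p in part])
            for part in set_partitions(sorted(g.nodes))
        )
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes)
        for _ in range(20):
            labels = rng.integers(0, 3, size=len(nodes))
            comms = [
                {n for n, l in zip(nodes, labels) if l == k}
                for k in range(3)
                if (labels == k).any()
            ]
            assert newman_modularity(g, comms) <= best + 1e-12


# ---------------------------------------------------------------------------
# edmot partition


class TestEdmotPartition:
    def test_two_cliques_recovered(self, two_cliques_net):
        cl = edmot_partition(two_cliques_net, min_cluster_size=3)
        assert sorted(sorted(c) for c in cl.clusters) == [
            ["A", "B", "C", "D"],
            ["E", "F", "G", "H"],
        ]

    def test_two_cliques_is_exhaustive_modularity_optimum(self, two_cliques_net):
        g = two_cliques_net.graph
        best_q, best_part = max(
            (newman_modularity(g, [set(p) for p in part]), part)
            for part in set_partitions(sorted(g.nodes))
        )
        assert sorted(sorted(c) for c in best_part) == [
            ["A", "B", "C", "D"],
            ["E", "F", "G", "H"],
        ]
        cl = edmot_partition(two_cliques_net, min_cluster_size=3)
        assert modularity(two_cliques_net, cl) == pytest.approx(best_q)

    def test_single_triangle_one_cluster(self):
        g = nx.complete_graph(["A", "B", "C"])
        cl = edmot_partition(Network(graph=g), min_cluster_size=3)
        assert cl.clusters == [{"A", "B", "C"}]

    def test_edgeless_network_all_dropped(self, gene_set_factory):
        net = build_graph(gene_set_factory(["A", "B", "C"]), edge_frame([]))
        cl = edmot_partition(net)
        assert cl.clusters == [] and cl.dropped == {"A", "B", "C"}

    def test_min_cluster_size_moves_small_clusters_to_dropped(self, two_cliques_net):
        cl = edmot_partition(two_cliques_net, min_cluster_size=5)
        assert cl.clusters == []
        assert cl.dropped == set(two_cliques_net.graph.nodes)

    @pytest.mark.parametrize("seed", range(10))
    def test_disjoint_and_covering_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(40, 0.1, seed=int(seed))
        g = nx.relabel_nodes(g, {n: f"N{n:02d}" for n in g.nodes})
        net = Network(graph=g)
        cl = edmot_partition(net, min_cluster_size=3)
        clustered = [n for c in cl.clusters for n in c]
        assert len(clustered) == len(set(clustered))  # disjoint
        assert set(clustered) | cl.dropped == set(g.nodes)  # coverage

    def test_deterministic_across_repeated_runs(self):
        g = nx.gnp_random_graph(30, 0.15, seed=7)
        g = nx.relabel_nodes(g, {n: f"N{n:02d}" for n in g.nodes})
        net = Network(graph=g)
        a = edmot_partition(net)
        b = edmot_partition(net)
        assert a.clusters == b.clusters and a.dropped == b.dropped

    @pytest.mark.parametrize("seed", range(5))
    def test_enhancement_never_removes_original_edges(self, seed):
        g = nx.gnp_random_graph(25, 0.2, seed=int(seed))
        g = nx.relabel_nodes(g, {n: f"N{n:02d}" for n in g.nodes})
        enhanced = edge_enhanced_graph(Network(graph=g))
        assert set(map(frozenset, g.edges)) <= set(map(frozenset, enhanced.edges))
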