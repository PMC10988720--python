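"""Network construction, overlapping clustering, and differencing."""

import itertools

import networkx as nx
import numpy as np
import pytest

from plomcon import (
    PlomconError,
    blockwise_adjacency,
    build_network,
    compare_network_grids,
    compare_networks,
    extract_dense_clusters,
    mean_degree,
    ocg_cluster,
)
from plomcon.graph import CovariationNetwork, _cluster_contribution


def _net(edges, nodes=None):
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    return CovariationNetwork(graph=G)


class TestBuildNetwork:
    def test_zero_matrix_gives_empty_edge_set(self):
        adj = blockwise_adjacency(np.eye(3), [("A", "n"), ("B", "n"), ("C", "n")])
        net = build_network(adj)
        assert net.edges == set() and set(net.nodes) == {"A", "B", "C"}

    def test_fully_connected_three_proteins(self):
        P = np.full((3, 3), 0.5)
        np.fill_diagonal(P, 1.0)
        adj = blockwise_adjacency(P, [("A", "n"), ("B", "n"), ("C", "n")])
        assert len(build_network(adj).edges) == 3

    def test_edge_set_equals_nonzero_pattern(self, rng):
        M = 6
        A = np.zeros((M, M))
        for i, j in itertools.combinations(range(M), 2):
            if rng.random() < 0.4:
                A[i, j] = A[j, i] = rng.normal()
        feats = [(f"P{i}", "n") for i in range(M)]
        adj = blockwise_adjacency(A + np.eye(M) * 0 + np.eye(M), feats)
        net = build_network(adj)
        expected = {(f"P{i}", f"P{j}") for i, j in itertools.combinations(range(M), 2)
                    if A[i, j] != 0}
        assert net.edges == expected

    def test_edge_annotations_carry_compartments(self):
        P = np.eye(2)
        P[0, 1] = P[1, 0] = -0.4
        adj = blockwise_adjacency(P, [("A", "nucleus"), ("B", "cytoplasm")])
        df = build_network(adj).edges_frame()
        assert df.loc[0, ["compartment_a", "compartment_b"]].tolist() == ["nucleus", "cytoplasm"]


class TestMeanDegree:
    def test_triangle_path_and_empty(self):
        tri = _net([(0, 1), (1, 2), (0, 2)])
        assert mean_degree(tri) == 2.0
        path = _net([(0, 1), (1, 2)])
        assert mean_degree(path) == pytest.approx(4 / 3)
        empty = _net([], nodes=range(5))
        assert mean_degree(empty) == 0.0

    def test_subset_counts_within_edges_only(self):
        net = _net([(0, 1), (1, 2), (0, 2), (2, 3)])
        assert mean_degree(net, [0, 1, 2]) == 2.0

    def test_empty_node_set_rejected(self):
        with pytest.raises(ValueError):
            mean_degree(_net([(0, 1)]), [])


class TestOCG:
    def test_two_disjoint_triangles_stay_separate(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        cs = ocg_cluster(net)
        assert sorted(sorted(c) for c in cs.clusters) == [[0, 1, 2], [3, 4, 5]]
        # brute force: best over {merged, separate} seed systems
        G = net.graph
        q_sep = sum(_cluster_contribution(G, frozenset(c), 12.0)
                    for c in ({0, 1, 2}, {3, 4, 5}))
        q_all = _cluster_contribution(G, frozenset(range(6)), 12.0)
        assert cs.modularity == pytest.approx(max(q_sep, q_all))

    def test_single_clique_is_one_cluster(self):
        cs = ocg_cluster(_net(itertools.combinations(range(4), 2)))
        assert [sorted(c) for c in cs.clusters] == [[0, 1, 2, 3]]

    def test_shared_node_belongs_to_both_clusters(self):
        net = _net([(0, 1), (1, 2), (0, 2), (2, 3), (3, 4), (2, 4)])
        cs = ocg_cluster(net)
        membership = [c for c in cs.clusters if 2 in c]
        assert len(membership) == 2

    def test_modularity_trace_never_decreases(self):
        rng = np.random.default_rng(0)
        G = nx.gnp_random_graph(20, 0.2, seed=4)
        G.add_edges_from(itertools.combinations(range(5), 2))  # planted dense module
        cs = ocg_cluster(CovariationNetwork(graph=G))
        assert np.all(np.diff(cs.modularity_trace) >= -1e-12)

    def test_edge_seeding_fallback_reaches_clique_modularity(self):
        # decomposing a clique into edge classes leaves modularity
        # unchanged, so strict-improvement merging keeps the edge seeds
        # but attains the same final modularity as clique seeding
        net = _net([(0, 1), (1, 2), (0, 2)])
        by_edges = ocg_cluster(net, init="edges")
        by_cliques = ocg_cluster(net, init="cliques")
        assert {frozenset(e) for e in net.graph.edges} == set(by_edges.clusters)
        assert by_edges.modularity == pytest.approx(by_cliques.modularity)

    def test_edgeless_network_rejected(self):
        with pytest.raises(PlomconError):
            ocg_cluster(_net([], nodes=range(3)))


class TestDenseExtraction:
    def test_triangle_kept_against_sparser_background(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4)])
        cs = ocg_cluster(net)
        dense = extract_dense_clusters(cs, net)
        assert mean_degree(net) < 2.0
        assert [sorted(c) for c in dense.clusters] == [[0, 1, 2]]

    def test_boundary_cluster_dropped_on_equality(self):
        # all clusters have mean degree equal to the network's -> none kept
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        cs = ocg_cluster(net)
        assert mean_degree(net) == 2.0
        assert extract_dense_clusters(cs, net).clusters == ()

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(1)
        G = nx.gnp_random_graph(15, 0.25, seed=2)
        G.add_edges_from(itertools.combinations(range(5), 2))
        net = CovariationNetwork(graph=G)
        cs = ocg_cluster(net)
        dense = extract_dense_clusters(cs, net)
        assert set(dense.clusters) <= set(cs.clusters)
        again = extract_dense_clusters(dense, net)
        assert again.clusters == dense.clusters

    def test_planted_dense_module_recovered_in_er_background(self):
        hits = 0
        n_trials = 25
        for seed in range(n_trials):
            G = nx.gnp_random_graph(24, 0.08, seed=seed)
            G.add_edges_from(itertools.combinations(range(6), 2))
            net = CovariationNetwork(graph=G)
            sub = G.subgraph(max(nx.connected_components(G), key=len))
            cs = ocg_cluster(CovariationNetwork(graph=nx.Graph(sub)))
            dense = extract_dense_clusters(cs, CovariationNetwork(graph=nx.Graph(sub)))
            hits += any(set(range(6)) <= c for c in dense.clusters)
        assert hits / n_trials >= 0.9


class TestCompareNetworks:
    def test_identical_networks_have_empty_difference(self):
        a = _net([("A", "B"), ("B", "C")], nodes="ABC")
        b = _net([("A", "B"), ("B", "C")], nodes="ABC")
        d = compare_networks(a, b)
        assert d.lost == set() and d.gained == set()
        assert d.retained == {("A", "B"), ("B", "C")}

    def test_control_only_edge_is_lost(self):
        a = _net([("A", "B")], nodes="AB")
        b = _net([], nodes="AB")
        assert compare_networks(a, b).lost == {("A", "B")}

    def test_antisymmetry(self):
        a = _net([("A", "B"), ("C", "D")], nodes="ABCD")
        b = _net([("A", "B"), ("B", "C")], nodes="ABCD")
        d1, d2 = compare_networks(a, b), compare_networks(b, a)
        assert d1.lost == d2.gained and d1.gained == d2.lost

    def test_node_universe_mismatch_rejected(self):
        with pytest.raises(PlomconError):
            compare_networks(_net([], nodes="AB"), _net([], nodes="ABC"))

    def test_grid_comparison_counts_multiplicity(self):
        ctrl = {0.9: _net([("A", "B")], nodes="AB"), 0.95: _net([("A", "B")], nodes="AB")}
        trt = {0.9: _net([], nodes="AB"), 0.95: _net([], nodes="AB")}
        d = compare_network_grids(ctrl, trt)
        assert d.lost == {("A", "B")}
        assert d.multiplicity[("A", "B")] == {"control": 2, "treated": 0}
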