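"""Weighted paths, centralities, central/peripheral rules, communities, stats."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from conftest import (
    brute_all_pairs,
    brute_centralities,
    exhaustive_best_partition,
    random_weighted_graph,
)
from foldbridges import analysis


def graph(edges, nodes=None):
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    for u, v, w in edges:
        G.add_edge(u, v, weight=w)
    return G


class TestShortestPaths:
    def test_single_edge_distance_is_reciprocal_weight(self):
        d = analysis.shortest_paths(graph([(0, 1, 0.5)]))
        assert d[0][1] == pytest.approx(2.0)

    def test_strong_two_hop_beats_weak_direct_edge(self):
        G = graph([(0, 1, 0.5), (0, 2, 2.0), (2, 1, 2.0)])
        d = analysis.shortest_paths(G)
        assert d[0][1] == pytest.approx(1.0)

    def test_infinite_across_components(self):
        d = analysis.shortest_paths(graph([(0, 1, 1.0)], nodes=[0, 1, 2]))
        assert math.isinf(d[0][2])

    def test_nonpositive_weight_rejected_before_traversal(self):
        with pytest.raises(ValueError, match="nonpositive"):
            analysis.shortest_paths(graph([(0, 1, -1.0)]))

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            G = random_weighted_graph(rng)
            dist = analysis.shortest_paths(G)
            oracle = brute_all_pairs(G)
            for s in G.nodes:
                for t in G.nodes:
                    assert dist[s][t] == pytest.approx(oracle[(s, t)][0])

    def test_metric_properties(self):
        rng = np.random.default_rng(2)
        G = random_weighted_graph(rng, n_max=7)
        d = analysis.shortest_paths(G)
        for i in G.nodes:
            for j in G.nodes:
                assert d[i][j] == pytest.approx(d[j][i])
                for k in G.nodes:
                    if all(map(math.isfinite, (d[i][k], d[k][j]))):
                        assert d[i][j] <= d[i][k] + d[k][j] + 1e-9


class TestCentralities:
    def test_degree_is_sum_of_incident_weights(self):
        G = graph([(0, 1, 0.5), (0, 2, 0.7)])
        cent = analysis.centralities(G).set_index("node")
        assert cent.loc[0, "degree"] == pytest.approx(1.2)

    def test_star_center_betweenness_counts_all_leaf_pairs(self):
        G = graph([("c", f"l{k}", 1.0) for k in range(4)])
        cent = analysis.centralities(G).set_index("node")
        assert cent.loc["c", "betweenness"] == pytest.approx(6.0)  # C(4,2)
        assert cent.loc["l0", "betweenness"] == 0.0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            G = random_weighted_graph(rng)
            cent = analysis.centralities(G).set_index("node")
            oracle = brute_centralities(G)
            for n in G.nodes:
                assert cent.loc[n, "degree"] == pytest.approx(oracle["degree"][n])
                assert cent.loc[n, "closeness"] == pytest.approx(oracle["closeness"][n])
                assert cent.loc[n, "betweenness"] == pytest.approx(oracle["betweenness"][n])

    def test_tree_betweenness_closed_form(self):
        # on a tree, betweenness of i = sum over branch pairs of s_a * s_b
        rng = np.random.default_rng(4)
        for seed in range(5):
            T = nx.random_labeled_tree(int(rng.integers(4, 12)), seed=seed)
            for u, v in T.edges:
                T[u][v]["weight"] = float(rng.uniform(0.2, 2.0))
            cent = analysis.centralities(T).set_index("node")
            for i in T.nodes:
                H = T.copy()
                H.remove_node(i)
                sizes = [len(c) for c in nx.connected_components(H)]
                expected = sum(
                    sizes[a] * sizes[b]
                    for a in range(len(sizes))
                    for b in range(a + 1, len(sizes))
                )
                assert cent.loc[i, "betweenness"] == pytest.approx(expected)

    def test_uniform_rescaling_behaviour(self):
        rng = np.random.default_rng(5)
        G = random_weighted_graph(rng)
        c = 3.7
        H = G.copy()
        for u, v in H.edges:
            H[u][v]["weight"] *= c
        a = analysis.centralities(G).set_index("node")
        b = analysis.centralities(H).set_index("node")
        for n in G.nodes:
            assert b.loc[n, "degree"] == pytest.approx(c * a.loc[n, "degree"])
            assert b.loc[n, "closeness"] == pytest.approx(c * a.loc[n, "closeness"])
            assert b.loc[n, "betweenness"] == pytest.approx(a.loc[n, "betweenness"])

    def test_adding_an_edge_never_increases_distances(self):
        rng = np.random.default_rng(6)
        G = random_weighted_graph(rng)
        d0 = analysis.shortest_paths(G)
        non_edges = [(u, v) for u in G.nodes for v in G.nodes if u < v and not G.has_edge(u, v)]
        if not non_edges:
            return
        u, v = non_edges[0]
        G.add_edge(u, v, weight=1.0)
        d1 = analysis.shortest_paths(G)
        for i in G.nodes:
            for j in G.nodes:
                assert d1[i][j] <= d0[i][j] + 1e-12


class TestCentralPeripheral:
    def test_top_thirty_percent_of_ten_is_three(self):
        G = graph([(k, k + 1, float(k + 1)) for k in range(9)])
        cent = analysis.centralities(G)
        parts = analysis.partition_central_peripheral(G, cent)
        assert len(parts["degree"]["central"]) == 3

    def test_isolated_node_is_peripheral_by_degree(self):
        G = graph([(0, 1, 1.0)], nodes=[0, 1, 2])
        parts = analysis.partition_central_peripheral(G, analysis.centralities(G))
        assert 2 in parts["degree"]["peripheral"]

    def test_tree_leaves_are_peripheral_by_betweenness(self):
        T = nx.balanced_tree(2, 3)
        for u, v in T.edges:
            T[u][v]["weight"] = 1.0
        parts = analysis.partition_central_peripheral(T, analysis.centralities(T))
        leaves = {n for n in T.nodes if T.degree(n) == 1}
        assert leaves <= parts["betweenness"]["peripheral"]

    def test_central_and_peripheral_disjoint_per_measure(self, small_bundle):
        from foldbridges.calibration import BridgeCalibration
        from foldbridges import networks

        ann = small_bundle.annotation
        table = small_bundle.score_tables["simA"]
        res = BridgeCalibration.from_score_table(table, ann).fit()
        alpha_of = ann.set_index("domain_id")["class"] == "a"
        pairs = table.frame[["domain_i", "domain_j"]].copy()
        pairs["score"] = table.frame["score"]
        alpha = (pairs["domain_i"].map(alpha_of) | pairs["domain_j"].map(alpha_of)).to_numpy()
        pairs["posterior"] = res.posterior(pairs["score"].to_numpy(), alpha)
        coll = networks.collapse(networks.assign_weights(pairs, "score"), ann, "fold")
        G = networks.build_static_network(coll, ann, 0.6, "simA")
        parts = analysis.partition_central_peripheral(G, analysis.centralities(G))
        for measure in analysis.MEASURES:
            assert not parts[measure]["central"] & parts[measure]["peripheral"]

    def test_boundary_ties_are_included(self):
        G = graph([("a", "b", 1.0), ("c", "d", 1.0), ("e", "f", 1.0)])
        parts = analysis.partition_central_peripheral(G, analysis.centralities(G))
        # all six nodes tie on degree 1.0; the tie at the boundary keeps them all
        assert parts["degree"]["central"] == set(G.nodes)


class TestCommunities:
    def test_two_cliques_joined_by_one_edge_split_in_two(self):
        G = nx.Graph()
        for base in (0, 5):
            for a in range(5):
                for b in range(a + 1, 5):
                    G.add_edge(base + a, base + b, weight=1.0)
        G.add_edge(0, 5, weight=1.0)
        part = analysis.detect_communities(G, seed=0)
        assert len(part.as_sets()) == 2
        assert {frozenset(s) for s in part.as_sets()} == {
            frozenset(range(5)),
            frozenset(range(5, 10)),
        }

    def test_single_clique_is_one_community(self):
        G = nx.complete_graph(6)
        for u, v in G.edges:
            G[u][v]["weight"] = 1.0
        part = analysis.detect_communities(G, seed=1)
        assert len(part.as_sets()) == 1

    def test_louvain_reaches_exhaustive_modularity_on_two_clique_graphs(self):
        for sizes in ((3, 3), (4, 4)):
            G = nx.Graph()
            base = 0
            for s in sizes:
                for a in range(s):
                    for b in range(a + 1, s):
                        G.add_edge(base + a, base + b, weight=1.0)
                base += s
            G.add_edge(0, sizes[0], weight=1.0)
            part = analysis.detect_communities(G, seed=2)
            best_q, _ = exhaustive_best_partition(G)
            assert part.modularity == pytest.approx(best_q)

    def test_empty_edge_set_warns_with_singleton_communities(self):
        G = nx.Graph()
        G.add_nodes_from("abc")
        with pytest.warns(UserWarning, match="empty edge set"):
            part = analysis.detect_communities(G)
        assert part.labels == {}


class TestStatistics:
    def test_triangle_clustering_is_one(self):
        G = graph([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        stats = analysis.network_statistics(G)
        assert stats["clustering_coefficient"] == 1.0

    def test_path_of_three_has_zero_clustering(self):
        G = graph([(0, 1, 1.0), (1, 2, 1.0)])
        assert analysis.network_statistics(G)["clustering_coefficient"] == 0.0

    def test_density_over_connected_nodes(self):
        G = graph([(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0)], nodes=[0, 1, 2, 3, 4])
        stats = analysis.network_statistics(G)
        assert stats["n_connected_nodes"] == 4
        assert stats["density"] == pytest.approx(3 / 6)

    def test_unique_edges_against_siblings(self):
        G = graph([(0, 1, 1.0), (1, 2, 1.0)])
        S = graph([(0, 1, 1.0)])
        stats = analysis.network_statistics(G, [S])
        assert stats["n_unique_edges"] == 1

    def test_component_counts(self):
        G = graph(
            [(0, 1, 1.0), (2, 3, 1.0)],
            nodes=list(range(6)),
        )
        stats = analysis.network_statistics(G)
        assert stats["n_components"] == 2
        assert stats["n_components_ge20"] == 0


class TestPivotal:
    def test_intersection_semantics(self):
        net1 = {m: {"central": {"a", "b"}, "peripheral": set()} for m in analysis.MEASURES}
        net2 = {m: {"central": {"a", "c"}, "peripheral": set()} for m in analysis.MEASURES}
        assert analysis.identify_pivotal([net1, net2]) == {"a"}

    def test_node_missing_from_one_central_set_is_not_pivotal(self):
        net1 = {m: {"central": {"a"}, "peripheral": set()} for m in analysis.MEASURES}
        net2 = {
            "degree": {"central": {"a"}, "peripheral": set()},
            "closeness": {"central": set(), "peripheral": set()},
            "betweenness": {"central": {"a"}, "peripheral": set()},
        }
        assert analysis.identify_pivotal([net1, net2]) == set()
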