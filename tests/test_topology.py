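import itertools

import networkx as nx
import numpy as np
import pytest

from trufflenet.network import CoNetwork
from trufflenet.topology import (
    ModulePartition,
    NodeTopology,
    avg_clustering,
    classify_roles,
    degree_centrality,
    density,
    detect_communities,
    modularity,
    participation_coefficient,
    summarize,
    within_module_z,
)


def _conet(G: nx.Graph, signs=None) -> CoNetwork:
    for i, (u, v) in enumerate(G.edges):
        G.edges[u, v].setdefault("sign", (signs or {}).get((u, v), 1))
        G.edges[u, v].setdefault("r", 0.5)
        G.edges[u, v].setdefault("q", 0.01)
    return CoNetwork(G)


def _all_partitions(nodes):
    """Independent set-partition enumeration (recursive, not RGS-based)."""
    nodes = list(nodes)
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for sub in _all_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


class TestDensity:
    def test_complete_graph_full_connectivity(self):
        assert density(nx.complete_graph(24)) == pytest.approx(100.0)

    def test_near_complete_23_nodes(self):
        G = nx.complete_graph(23)
        G.remove_edges_from(list(G.edges)[:3])  # 250 of 253 edges
        assert round(density(G), 1) == 98.8

    def test_empty_graph(self):
        G = nx.empty_graph(5)
        assert density(G) == pytest.approx(0.0)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            density(nx.empty_graph(1))


class TestClustering:
    def test_complete_graph_maximum(self):
        assert avg_clustering(nx.complete_graph(24)) == pytest.approx(100.0)

    def test_path_has_no_triangles(self):
        assert avg_clustering(nx.path_graph(3)) == pytest.approx(0.0)

    def test_triangle_plus_pendant(self):
        G = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        # c has 3 neighbors and 1 closed pair -> 1/3; a, b stay 1; d deg-1 -> 0
        assert avg_clustering(G) == pytest.approx(100 * (1 + 1 + 1 / 3 + 0) / 4)

    def test_matches_brute_force_triangle_counts(self, rng):
        """Local clustering equals triangles/(neighbor pairs) enumerated
        directly, on random graphs up to 12 nodes."""
        for trial in range(20):
            n = int(rng.integers(4, 13))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)),
                                    seed=int(rng.integers(0, 2**31)))
            locals_ = []
            for v in G.nodes:
                nbrs = list(G.neighbors(v))
                if len(nbrs) < 2:
                    locals_.append(0.0)
                    continue
                tri = sum(1 for a, b in itertools.combinations(nbrs, 2)
                          if G.has_edge(a, b))
                locals_.append(tri / (len(nbrs) * (len(nbrs) - 1) / 2))
            assert avg_clustering(G) == pytest.approx(100 * np.mean(locals_))


class TestCommunities:
    def test_disjoint_triangles_split_by_component(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = detect_communities(G)
        assert part.n_modules == 2
        assert part.assignment[0] == part.assignment[1] == part.assignment[2]
        assert part.assignment[3] == part.assignment[4] == part.assignment[5]

    def test_complete_graph_single_module(self):
        part = detect_communities(nx.complete_graph(24))
        assert part.n_modules == 1

    def test_two_cliques_with_bridge(self):
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        G.add_edge(0, 5)
        part = detect_communities(G)
        assert part.n_modules == 2
        assert {part.assignment[i] for i in range(5)} != \
               {part.assignment[i] for i in range(5, 10)}

    def test_isolated_nodes_become_singletons(self):
        G = nx.Graph([(0, 1)])
        G.add_nodes_from([7, 8])
        part = detect_communities(G)
        assert part.assignment[7] != part.assignment[8]
        assert part.n_modules == 3

    def test_edgeless_graph(self):
        part = detect_communities(nx.empty_graph(4))
        assert part.n_modules == 4

    def test_attains_exhaustive_maximum_on_small_graphs(self, rng):
        """The detected partition's Q equals the maximum over ALL set
        partitions, for random graphs with up to 8 nodes."""
        for trial in range(25):
            n = int(rng.integers(3, 9))
            G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.9)),
                                    seed=int(rng.integers(0, 2**31)))
            if G.number_of_edges() == 0:
                continue
            part = detect_communities(G)
            q_detected = modularity(G, part)
            q_best = max(
                nx.community.modularity(G, [set(g) for g in grouping])
                for grouping in _all_partitions(list(G.nodes))
            )
            assert q_detected == pytest.approx(q_best, abs=1e-9)

    def test_deterministic(self):
        G = nx.gnp_random_graph(15, 0.3, seed=99)
        a = detect_communities(G).assignment
        b = detect_communities(G).assignment
        assert a == b


class TestModularity:
    def test_single_module_partition_is_zero(self):
        G = nx.gnp_random_graph(9, 0.5, seed=3)
        part = ModulePartition.single_module(list(G.nodes))
        assert modularity(G, part) == pytest.approx(0.0, abs=1e-12)

    def test_two_disjoint_triangles(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = ModulePartition.from_groups([[0, 1, 2], [3, 4, 5]])
        assert modularity(G, part) == pytest.approx(0.5)

    def test_two_triangles_joined_by_edge(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)])
        part = ModulePartition.from_groups([[0, 1, 2], [3, 4, 5]])
        assert modularity(G, part) == pytest.approx(5 / 14)

    def test_edgeless_graph_warns_and_returns_zero(self):
        G = nx.empty_graph(3)
        with pytest.warns(UserWarning):
            q = modularity(G, ModulePartition.single_module(list(G.nodes)))
        assert q == 0.0

    def test_partition_must_cover_nodes(self):
        G = nx.Graph([(0, 1)])
        with pytest.raises(ValueError, match="cover"):
            modularity(G, ModulePartition({0: 0}))


class TestDegreeCentrality:
    def test_complete_graph_node(self):
        assert degree_centrality(nx.complete_graph(5))[0] == pytest.approx(1.0)

    def test_isolated_node(self):
        G = nx.Graph([(0, 1)])
        G.add_node(2)
        assert degree_centrality(G)[2] == pytest.approx(0.0)

    def test_degree_three_in_seven_node_graph(self):
        G = nx.empty_graph(7)
        G.add_edges_from([(0, 1), (0, 2), (0, 3)])
        assert degree_centrality(G)[0] == pytest.approx(0.5)


class TestZiPi:
    def test_three_node_star_module_extremes(self):
        G = nx.Graph([("a", "b"), ("a", "c")])
        zi = within_module_z(G, ModulePartition.single_module(["a", "b", "c"]))
        assert round(zi["a"], 3) == 1.414
        assert round(zi["b"], 3) == round(zi["c"], 3) == -0.707

    def test_three_node_single_edge_module(self):
        G = nx.Graph([("b", "c")])
        G.add_node("a")
        zi = within_module_z(G, ModulePartition.single_module(["a", "b", "c"]))
        assert round(zi["a"], 3) == -1.414
        assert round(zi["b"], 3) == round(zi["c"], 3) == 0.707

    def test_homogeneous_module_all_zero(self):
        zi = within_module_z(nx.complete_graph(24),
                             ModulePartition.single_module(range(24)))
        assert all(v == 0.0 for v in zi.values())

    def test_zi_sums_to_zero_within_spread_modules(self, rng):
        G = nx.gnp_random_graph(12, 0.4, seed=11)
        part = detect_communities(G)
        zi = within_module_z(G, part)
        for members in part.modules():
            k = [sum(1 for nb in G.neighbors(n) if part.assignment[nb] ==
                     part.assignment[n]) for n in members]
            if len(members) >= 2 and np.std(k) > 0:
                assert sum(zi[n] for n in members) == pytest.approx(0, abs=1e-9)

    def test_all_neighbors_in_own_module(self):
        G = nx.complete_graph(4)
        pi = participation_coefficient(G, ModulePartition.single_module(range(4)))
        assert all(v == 0.0 for v in pi.values())

    def test_degree_three_across_three_modules(self):
        G = nx.Graph([("i", "x"), ("i", "y"), ("i", "z")])
        part = ModulePartition({"i": 0, "x": 0, "y": 1, "z": 2})
        pi = participation_coefficient(G, part)
        assert round(pi["i"], 3) == 0.667

    def test_degree_two_split_across_two_modules(self):
        G = nx.Graph([("i", "x"), ("i", "y")])
        part = ModulePartition({"i": 0, "x": 0, "y": 1})
        assert participation_coefficient(G, part)["i"] == pytest.approx(0.5)

    def test_pi_bounded_by_modules_touched(self, rng):
        G = nx.gnp_random_graph(14, 0.35, seed=5)
        part = detect_communities(G)
        pi = participation_coefficient(G, part)
        for n in G.nodes:
            touched = {part.assignment[nb] for nb in G.neighbors(n)}
            c = max(len(touched), 1)
            assert -1e-12 <= pi[n] <= 1 - 1 / c + 1e-12

    def test_isolated_node_pi_zero(self):
        G = nx.Graph([(0, 1)])
        G.add_node(2)
        part = ModulePartition({0: 0, 1: 0, 2: 1})
        assert participation_coefficient(G, part)[2] == 0.0


class TestRoles:
    @pytest.mark.parametrize("zi,pi,role", [
        (0.0, 0.0, "peripheral"),
        (3.0, 0.1, "module_hub"),
        (0.5, 0.7, "connector"),
        (3.0, 0.7, "network_hub"),
        (2.5, 0.62, "module_hub"),  # boundary: zi >= cut, pi <= cut
    ])
    def test_quadrants(self, zi, pi, role):
        (out,) = classify_roles([NodeTopology("n", 3, 0.5, zi, pi, 0)])
        assert out.role == role


class TestSummarize:
    def test_complete_graph_summary(self):
        net = _conet(nx.complete_graph(24))
        s = summarize(net)
        assert s.density_pct == 100.0
        assert s.avg_clustering_pct == 100.0
        assert s.n_modules == 1
        assert s.zi_range == (0.0, 0.0)
        assert s.pi_range == (0.0, 0.0)
        assert s.n_edges == s.n_positive == 276

    def test_edge_sign_tallies(self):
        G = nx.Graph()
        G.add_edge("a", "b", sign=1, r=0.5, q=0.01)
        G.add_edge("b", "c", sign=-1, r=-0.5, q=0.01)
        s = summarize(CoNetwork(G))
        assert (s.n_positive, s.n_negative) == (1, 1)
        assert s.n_edges == s.n_positive + s.n_negative

    def test_empty_graph_degenerate(self):
        net = _conet(nx.empty_graph(3))
        with pytest.warns(UserWarning):
            s = summarize(net)
        assert s.density_pct == 0.0
        assert s.avg_clustering_pct == 0.0
        assert s.modularity == 0.0
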