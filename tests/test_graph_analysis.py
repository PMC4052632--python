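import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from isfc.fc_stats import pairwise_correlation_matrix
from isfc.graph_analysis import (
    build_fc_graph,
    d1_dissimilarity_matrix,
    degree_centrality,
    hierarchical_clustering,
    kamada_kawai_layout,
    signed_adjacency,
    write_graphml,
    write_pajek,
)


def graph_from_signed_edges(n, edges):
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, name=f"n{i}", index=i)
    for u, v, sign in edges:
        g.add_edge(u, v, sign=sign, weight=0.9 * sign)
    return g


class TestBuildFcGraph:
    def test_no_significant_pairs_edgeless(self):
        rng = np.random.default_rng(0)
        # nearly orthogonal deterministic columns -> no significant pair
        data = pd.DataFrame(np.eye(8, 4) + 0.01 * rng.standard_normal((8, 4)))
        fc = pairwise_correlation_matrix(data, alpha=1e-6)
        g = build_fc_graph(fc)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 0

    def test_all_pairs_significant_complete(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(10)
        data = pd.DataFrame({f"c{i}": base + 0.01 * rng.standard_normal(10) for i in range(5)})
        fc = pairwise_correlation_matrix(data)
        g = build_fc_graph(fc)
        assert g.number_of_edges() == 5 * 4 // 2

    def test_exactly_the_planted_pairs_pass(self):
        # 4-ROI toy: columns 0/1 and 2/3 strongly coupled, cross pairs near 0
        rng = np.random.default_rng(2)
        v = rng.standard_normal(12)
        w = rng.standard_normal(12)
        w -= v * (v @ w) / (v @ v)  # exactly orthogonal to v
        data = pd.DataFrame(
            {
                "a": v,
                "b": v + 0.05 * rng.standard_normal(12),
                "c": w,
                "d": w + 0.05 * rng.standard_normal(12),
            }
        )
        fc = pairwise_correlation_matrix(data, alpha=0.001)
        g = build_fc_graph(fc)
        assert set(map(frozenset, g.edges())) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_edge_signs_follow_r(self):
        rng = np.random.default_rng(3)
        v = rng.standard_normal(12)
        data = pd.DataFrame({"a": v, "b": v, "c": -v})
        fc = pairwise_correlation_matrix(data)
        g = build_fc_graph(fc)
        assert g.edges[0, 1]["sign"] == 1
        assert g.edges[0, 2]["sign"] == -1

    def test_undefined_correlations_give_no_edge(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning):
            fc = pairwise_correlation_matrix(
                pd.DataFrame({"a": np.full(8, 1.0), "b": rng.standard_normal(8), "c": rng.standard_normal(8)})
            )
        g = build_fc_graph(fc)
        assert not any(0 in e for e in g.edges())


class TestDegreeCentrality:
    def test_isolated_node_zero(self):
        g = graph_from_signed_edges(3, [(0, 1, 1)])
        assert degree_centrality(g)[2] == 0

    def test_complete_graph(self):
        g = graph_from_signed_edges(5, [(u, v, 1) for u, v in itertools.combinations(range(5), 2)])
        assert all(d == 4 for d in degree_centrality(g).values())

    def test_star_on_6_nodes(self):
        g = graph_from_signed_edges(6, [(0, v, 1) for v in range(1, 6)])
        degrees = degree_centrality(g)
        assert degrees[0] == 5
        assert all(degrees[v] == 1 for v in range(1, 6))

    def test_sign_agnostic(self):
        g = graph_from_signed_edges(3, [(0, 1, 1), (0, 2, -1)])
        assert degree_centrality(g)[0] == 2


class TestD1Dissimilarity:
    def test_structurally_equivalent_nodes_zero(self):
        # 0 and 1 both connect (only) to 2 and 3 with the same signs
        g = graph_from_signed_edges(4, [(0, 2, 1), (1, 2, 1), (0, 3, -1), (1, 3, -1)])
        d1 = d1_dissimilarity_matrix(g)
        assert d1[0, 1] == 0.0

    def test_star_center_vs_leaf_is_one(self):
        n = 7
        g = graph_from_signed_edges(n, [(0, v, 1) for v in range(1, n)])
        d1 = d1_dissimilarity_matrix(g)
        # centre links every third node, a leaf links none of them
        assert d1[0, 1] == pytest.approx(1.0)

    def test_opposite_signs_count_as_difference(self):
        g = graph_from_signed_edges(3, [(0, 2, 1), (1, 2, -1)])
        d1 = d1_dissimilarity_matrix(g)
        assert d1[0, 1] == pytest.approx(1.0)  # single third node, labels differ

    def test_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(5)
        g = nx.gnp_random_graph(8, 0.4, seed=3)
        for u, v in g.edges():
            g.edges[u, v]["sign"] = int(rng.choice([-1, 1]))
        d1 = d1_dissimilarity_matrix(g)
        assert np.allclose(d1, d1.T)
        assert np.allclose(np.diag(d1), 0.0)
        assert d1.min() >= 0 and d1.max() <= 1

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            for u, v in g.edges():
                g.edges[u, v]["sign"] = int(rng.choice([-1, 1]))
            adj = signed_adjacency(g)
            d1 = d1_dissimilarity_matrix(g)
            for u in range(n):
                for v in range(n):
                    if u == v:
                        continue
                    count = sum(
                        1 for w in range(n) if w not in (u, v) and adj[u, w] != adj[v, w]
                    )
                    assert d1[u, v] == pytest.approx(count / (n - 2))

    def test_triangle_inequality_on_small_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e6)))
            for u, v in g.edges():
                g.edges[u, v]["sign"] = int(rng.choice([-1, 1]))
            d1 = d1_dissimilarity_matrix(g)
            for u, v, w in itertools.permutations(range(n), 3):
                # pseudo-metric on profiles, up to the excluded-position slack
                assert d1[u, w] <= d1[u, v] + d1[v, w] + 2.0 / (n - 2) + 1e-12

    def test_too_few_nodes_error(self):
        g = graph_from_signed_edges(2, [(0, 1, 1)])
        with pytest.raises(ValueError):
            d1_dissimilarity_matrix(g)


class TestHierarchicalClustering:
    def test_two_cliques_recovered_at_k2(self):
        edges = [(u, v, 1) for u, v in itertools.combinations(range(4), 2)]
        edges += [(u, v, 1) for u, v in itertools.combinations(range(4, 8), 2)]
        g = graph_from_signed_edges(8, edges)
        d1 = d1_dissimilarity_matrix(g)
        # within-clique profiles agree except at the excluded positions
        dend = hierarchical_clustering(d1)
        labels = dend.cut(2)
        assert len(set(labels[:4])) == 1
        assert len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    def test_single_node_trivial_tree(self):
        dend = hierarchical_clustering(np.zeros((1, 1)), labels=["only"])
        assert dend.cut(1).tolist() == [1]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((10, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dend = hierarchical_clustering(d)
        assert np.all(np.diff(dend.heights) >= -1e-12)

    def test_asymmetric_input_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_clustering(d)

    def test_newick_export_parses(self):
        import dendropy

        rng = np.random.default_rng(9)
        x = rng.standard_normal((6, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dend = hierarchical_clustering(d, labels=[f"L{i}" for i in range(6)])
        tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
        assert len(tree.leaf_nodes()) == 6


class TestKamadaKawaiLayout:
    def test_single_node_at_origin(self):
        g = nx.Graph()
        g.add_node(0)
        lay = kamada_kawai_layout(g)
        assert np.allclose(lay.coords, 0.0)

    def test_single_edge_distance_near_ideal(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        lay = kamada_kawai_layout(g, seed=3)
        d = np.linalg.norm(lay.coords[0] - lay.coords[1])
        assert d == pytest.approx(1.0, rel=0.01)

    def test_three_node_path_collinear_optimum(self):
        lay = kamada_kawai_layout(nx.path_graph(3), seed=1)
        d01 = np.linalg.norm(lay.coords[0] - lay.coords[1])
        d02 = np.linalg.norm(lay.coords[0] - lay.coords[2])
        assert d02 == pytest.approx(2 * d01, rel=0.05)

    def test_energy_monotone_and_below_initial(self):
        g = nx.gnp_random_graph(12, 0.3, seed=5)
        lay = kamada_kawai_layout(g, seed=7)
        assert np.all(np.diff(lay.energies) <= 0)
        assert lay.energy <= lay.energies[0]

    def test_reproducible_given_seed(self):
        g = nx.gnp_random_graph(10, 0.4, seed=2)
        a = kamada_kawai_layout(g, seed=11)
        b = kamada_kawai_layout(g, seed=11)
        assert np.array_equal(a.coords, b.coords)

    @pytest.mark.parametrize("seed", range(10))
    def test_two_cliques_bridge_separation(self, seed):
        g = nx.Graph()
        for u, v in itertools.combinations(range(5), 2):
            g.add_edge(u, v)
        for u, v in itertools.combinations(range(5, 10), 2):
            g.add_edge(u, v)
        g.add_edge(0, 5)
        lay = kamada_kawai_layout(g, seed=seed)
        intra, inter = [], []
        for u, v in itertools.combinations(range(10), 2):
            d = np.linalg.norm(lay.coords[u] - lay.coords[v])
            if (u < 5) == (v < 5):
                intra.append(d)
            else:
                inter.append(d)
        assert np.mean(intra) < np.mean(inter)

    def test_disconnected_graph_finite(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_node(2)
        lay = kamada_kawai_layout(g, seed=0)
        assert np.all(np.isfinite(lay.coords))


class TestExports:
    def test_pajek_and_graphml_round_trip(self, tmp_path):
        g = graph_from_signed_edges(4, [(0, 1, 1), (2, 3, -1)])
        write_pajek(g, tmp_path / "g.net")
        write_graphml(g, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_edges() == 2
        net = (tmp_path / "g.net").read_text()
        assert "*vertices" in net.lower()
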