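from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from healthspace.rdd import DegenerateInputError
from healthspace.space import (
    ProximityMatrix,
    added_edge_count,
    build_country_disease_graph,
    build_disease_space,
    compute_proximity,
    max_spanning_tree,
)
from healthspace.io_panel import CountryDiseaseMatrix
from healthspace.synthetic import generate_world
from healthspace.rdd import binarize, compute_rdd

from .conftest import random_incidence


def proximity_conditional_oracle(M):
    """min of the two conditional co-occurrence probabilities, by counting."""
    M = np.asarray(M)
    k = M.shape[1]
    Phi = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            both = int(np.sum(M[:, i] * M[:, j]))
            p_i_given_j = both / M[:, j].sum()
            p_j_given_i = both / M[:, i].sum()
            Phi[i, j] = min(p_i_given_j, p_j_given_i)
    return Phi


class TestProximity:
    def test_hand_example(self):
        Phi = compute_proximity(np.array([[1, 1], [1, 0]]))
        assert Phi.Phi[0, 1] == pytest.approx(0.5)

    def test_identical_columns_give_certainty(self):
        Phi = compute_proximity(np.array([[1, 1], [1, 1], [0, 0]]))
        assert Phi.Phi[0, 1] == pytest.approx(1.0)

    def test_disjoint_columns_give_zero(self):
        Phi = compute_proximity(np.array([[1, 0], [0, 1]]))
        assert Phi.Phi[0, 1] == 0.0

    def test_zero_ubiquity_errors(self):
        with pytest.raises(DegenerateInputError):
            compute_proximity(np.array([[1, 0], [1, 0]]))

    def test_matches_conditional_probability_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            M = random_incidence(rng, 6, 8)
            np.testing.assert_allclose(
                compute_proximity(M).Phi, proximity_conditional_oracle(M), atol=1e-12
            )


def brute_force_max_tree_weight(graph):
    """Maximum total weight over all spanning trees, by enumeration."""
    edges = list(graph.edges(data="weight"))
    n = graph.number_of_nodes()
    best = None
    for subset in combinations(edges, n - 1):
        sub = nx.Graph()
        sub.add_nodes_from(graph.nodes())
        sub.add_weighted_edges_from(subset)
        if nx.is_connected(sub):
            w = sum(w for _, _, w in subset)
            best = w if best is None else max(best, w)
    return best


class TestMaxSpanningTree:
    def test_triangle_drops_lightest_edge(self):
        W = np.array([[0, 3, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        tree = max_spanning_tree(W, labels=list("abc"))
        assert sorted(w for _, _, w in tree) == [2.0, 3.0]

    def test_tree_input_is_identity(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 5.0), ("b", "d", 2.0)])
        tree = max_spanning_tree(g)
        assert sorted((min(u, v), max(u, v)) for u, v, _ in tree) == sorted(
            (min(u, v), max(u, v)) for u, v in g.edges()
        )

    def test_matches_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 25:
            n = int(rng.integers(3, 7))
            W = rng.uniform(0.1, 5.0, size=(n, n))
            W = np.triu(W, 1) * (rng.uniform(size=(n, n)) < 0.7)
            W = W + W.T
            g = nx.Graph()
            g.add_nodes_from(range(n))
            ii, jj = np.nonzero(np.triu(W, 1))
            g.add_weighted_edges_from((int(i), int(j), W[i, j]) for i, j in zip(ii, jj))
            if not nx.is_connected(g):
                continue
            tree = max_spanning_tree(g)
            assert sum(w for _, _, w in tree) == pytest.approx(
                brute_force_max_tree_weight(g)
            )
            checked += 1

    def test_disconnected_graph_warns_or_errors(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 2.0
        with pytest.warns(UserWarning, match="disconnected"):
            forest = max_spanning_tree(W)
        assert len(forest) == 2
        with pytest.raises(ValueError):
            max_spanning_tree(W, on_disconnected="error")

    def test_deterministic_under_ties(self):
        W = np.ones((4, 4)) - np.eye(4)
        t1 = max_spanning_tree(W, labels=list("abcd"))
        t2 = max_spanning_tree(W, labels=list("abcd"))
        assert t1 == t2


def synthetic_proximity(k=100, seed=7):
    world = generate_world(l=60, k=k, noise=0.05, seed=seed)
    M = binarize(compute_rdd(world.E))
    return compute_proximity(M)


class TestDiseaseSpace:
    def test_closed_form_added_edge_count(self):
        Phi = synthetic_proximity()
        k = len(Phi.diseases)
        net = build_disease_space(Phi, target_avg_degree=4.0)
        added = [
            (u, v, d["weight"])
            for u, v, d in net.edges(data=True)
            if not d["in_mst"]
        ]
        assert 2 * net.number_of_edges() / k >= 4.0
        assert len(added) == added_edge_count(k, 4.0)
        # MST is a subgraph
        mst_edges = [e for *e, d in net.edges(data=True) if d["in_mst"]]
        assert len(mst_edges) == k - 1
        # removing the weakest added link drops back below the target
        assert 2 * (net.number_of_edges() - 1) / k < 4.0

    def test_target_at_mst_degree_returns_mst(self):
        Phi = synthetic_proximity(k=40, seed=3)
        k = len(Phi.diseases)
        net = build_disease_space(Phi, target_avg_degree=2 * (k - 1) / k)
        assert net.number_of_edges() == k - 1
        assert all(d["in_mst"] for _, _, d in net.edges(data=True))

    def test_three_node_complete_graph_target_two(self):
        Phi = ProximityMatrix(
            np.array([[0, 0.9, 0.5], [0.9, 0, 0.2], [0.5, 0.2, 0]]),
            diseases=list("abc"),
        )
        net = build_disease_space(Phi, target_avg_degree=2.0)
        assert net.number_of_edges() == 3  # MST (2 edges) + the one remaining

    def test_target_below_tree_rejected(self):
        Phi = synthetic_proximity(k=40, seed=3)
        with pytest.raises(ValueError):
            build_disease_space(Phi, target_avg_degree=1.0)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        M = random_incidence(rng, 12, 10)
        Phi = compute_proximity(M)
        perm = rng.permutation(10)
        Phi_p = ProximityMatrix(
            Phi.Phi[np.ix_(perm, perm)], [Phi.diseases[i] for i in perm]
        )
        net = build_disease_space(Phi, 4.0)
        net_p = build_disease_space(Phi_p, 4.0)
        assert set(map(frozenset, net.edges())) == set(map(frozenset, net_p.edges()))


class TestBipartiteGraph:
    @staticmethod
    def _matrix(arr, l_labels, k_labels):
        return CountryDiseaseMatrix(
            E=np.asarray(arr, dtype=float),
            countries=l_labels,
            diseases=k_labels,
            year=2016,
            age_mode="all_ages",
        )

    def test_hand_example_three_edges_form_tree(self):
        E = self._matrix([[1.0, 2.0], [0.0, 3.0]], ["c1", "c2"], ["d1", "d2"])
        g = build_country_disease_graph(E)
        assert g.number_of_edges() == 3
        assert all(d["in_mst"] for _, _, d in g.edges(data=True))

    def test_zero_cell_has_no_edge(self):
        E = self._matrix([[1.0, 0.0], [2.0, 3.0]], ["c1", "c2"], ["d1", "d2"])
        g = build_country_disease_graph(E)
        assert not g.has_edge("C::c1", "D::d2")

    def test_mst_edge_count_on_random_dense_matrix(self):
        rng = np.random.default_rng(4)
        E = self._matrix(
            rng.uniform(0.1, 5.0, size=(5, 8)),
            [f"c{i}" for i in range(5)],
            [f"d{j}" for j in range(8)],
        )
        g = build_country_disease_graph(E)
        assert sum(d["in_mst"] for _, _, d in g.edges(data=True)) == 12  # l + k - 1
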