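"""Hypergraph construction, weights, adjacency matrices and centrality."""
import itertools

import numpy as np
import pytest

from hypermorb import (
    DegenerateGraphError,
    DiseaseCatalog,
    UndefinedWeightError,
    build_incidence,
    dual_adjacency,
    enumerate_hyperedges,
    eigenvector_centrality,
    node_adjacency,
    overlap_weight,
    power_iteration,
    rank_centralities,
)
from hypermorb.hypergraph import AdjacencyMatrix, CentralityTable


def brute_force_edges(matrix):
    """Independent oracle: distinct observed profiles of size >= 2 with
    superset member counts, via plain Python loops."""
    rows = [frozenset(np.flatnonzero(r)) for r in np.asarray(matrix)]
    profiles = {p for p in rows if len(p) >= 2}
    return {
        tuple(sorted(p)): sum(1 for r in rows if p <= r)
        for p in profiles
    }


def brute_force_node_adjacency(inc):
    """Oracle: per-edge accumulation with an explicit double loop."""
    n = len(inc.catalog)
    A = np.zeros((n, n))
    for e, w in zip(inc.edges, inc.W_E):
        for i in e.indices:
            for j in e.indices:
                if i != j:
                    A[i, j] += w
    return A


def brute_force_dual_adjacency(inc):
    m = inc.n_edges
    A = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            shared = set(inc.edges[a].indices) & set(inc.edges[b].indices)
            A[a, b] = inc.W_E[a] * sum(inc.W_N[d] for d in shared) * inc.W_E[b]
    return A


class TestEnumeration:
    def test_toy_profiles_and_supports(self, toy_matrix, toy_catalog):
        edges = enumerate_hyperedges(toy_matrix, toy_catalog)
        by_set = {e.diseases: e for e in edges}
        assert set(by_set) == {("hypertension", "obesity"),
                              ("hypertension", "obesity", "diabetes")}
        assert by_set[("hypertension", "obesity")].member_count == 3
        assert by_set[("hypertension", "obesity", "diabetes")].member_count == 1

    def test_single_disease_profiles_give_no_edges(self, toy_catalog):
        m = np.eye(3, dtype=np.int8)
        assert enumerate_hyperedges(m, toy_catalog) == []

    def test_row_order_invariance(self, toy_matrix, toy_catalog):
        rng = np.random.default_rng(1)
        shuffled = toy_matrix[rng.permutation(len(toy_matrix))]
        assert enumerate_hyperedges(shuffled, toy_catalog) == \
            enumerate_hyperedges(toy_matrix, toy_catalog)

    def test_matches_brute_force_on_random_matrices(self):
        catalog = DiseaseCatalog(tuple(f"d{i}" for i in range(6)))
        rng = np.random.default_rng(2024)
        for _ in range(25):
            m = (rng.random((rng.integers(1, 30), 6)) < 0.35).astype(np.int8)
            edges = enumerate_hyperedges(m, catalog)
            oracle = brute_force_edges(m)
            assert {e.indices: e.member_count for e in edges} == oracle

    def test_canonical_ordering(self, toy_matrix, toy_catalog):
        edges = enumerate_hyperedges(toy_matrix, toy_catalog)
        keys = [(len(e.indices), e.indices) for e in edges]
        assert keys == sorted(keys)

    def test_subset_closure_universe_contains_profile_edges(self, toy_matrix, toy_catalog):
        profiles = {e.indices for e in enumerate_hyperedges(toy_matrix, toy_catalog)}
        closure = {e.indices
                   for e in enumerate_hyperedges(toy_matrix, toy_catalog,
                                                 edge_universe="subsets")}
        assert profiles <= closure
        assert (0, 2) in closure  # {H, D} is a subset of the observed triple

    def test_exact_counting_mode(self, toy_matrix, toy_catalog):
        edges = enumerate_hyperedges(toy_matrix, toy_catalog, counting="exact")
        by_set = {e.diseases: e.member_count for e in edges}
        assert by_set[("hypertension", "obesity")] == 2  # the triple no longer counts


class TestOverlapWeight:
    def test_toy_weights(self, toy_matrix):
        # H=4, O=3, both=3 -> 3/3; all three=1, min=2 -> 1/2
        assert overlap_weight((0, 1), toy_matrix) == 1.0
        assert overlap_weight((0, 1, 2), toy_matrix) == 0.5

    def test_perfectly_nested_pair(self):
        m = np.array([[1, 1]], dtype=np.int8)
        assert overlap_weight((0, 1), m) == 1.0

    def test_zero_case_disease_is_an_error(self):
        m = np.array([[1, 0], [1, 0]], dtype=np.int8)
        with pytest.raises(UndefinedWeightError):
            overlap_weight((0, 1), m)

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(7)
        catalog = DiseaseCatalog(tuple(f"d{i}" for i in range(5)))
        for _ in range(20):
            m = (rng.random((20, 5)) < 0.5).astype(np.int8)
            for e in enumerate_hyperedges(m, catalog):
                assert 0.0 < e.weight <= 1.0


class TestAdjacency:
    def test_single_edge_node_adjacency(self):
        catalog = DiseaseCatalog(("a", "b"))
        inc = build_incidence(np.array([[1, 1]], dtype=np.int8), catalog)
        A = node_adjacency(inc).values
        assert A[0, 1] == A[1, 0] == pytest.approx(1.0)
        assert A[0, 0] == A[1, 1] == 0.0

    def test_toy_node_adjacency(self, toy_matrix, toy_catalog):
        inc = build_incidence(toy_matrix, toy_catalog)
        expected = np.array([[0.0, 1.5, 0.5],
                             [1.5, 0.0, 0.5],
                             [0.5, 0.5, 0.0]])
        np.testing.assert_allclose(node_adjacency(inc).values, expected)

    def test_toy_dual_adjacency(self, toy_matrix, toy_catalog):
        inc = build_incidence(toy_matrix, toy_catalog)
        np.testing.assert_allclose(inc.W_N, [0.8, 0.6, 0.4])
        np.testing.assert_allclose(dual_adjacency(inc).values,
                                   [[0.0, 0.7], [0.7, 0.0]])

    def test_disjoint_edges_have_zero_dual_adjacency(self):
        catalog = DiseaseCatalog(("a", "b", "c", "d"))
        m = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        inc = build_incidence(m, catalog)
        assert (dual_adjacency(inc).values == 0).all()

    def test_single_edge_dual_is_1x1_zero(self):
        catalog = DiseaseCatalog(("a", "b"))
        inc = build_incidence(np.array([[1, 1]], dtype=np.int8), catalog)
        assert dual_adjacency(inc).values.shape == (1, 1)
        assert dual_adjacency(inc).values[0, 0] == 0.0

    def test_oracle_equivalence_random_instances(self):
        catalog = DiseaseCatalog(tuple(f"d{i}" for i in range(6)))
        rng = np.random.default_rng(99)
        for _ in range(30):
            m = (rng.random((30, 6)) < 0.4).astype(np.int8)
            inc = build_incidence(m, catalog)
            assert np.abs(node_adjacency(inc).values
                          - brute_force_node_adjacency(inc)).max() <= 1e-12
            assert np.abs(dual_adjacency(inc).values
                          - brute_force_dual_adjacency(inc)).max() <= 1e-12

    def test_symmetry_and_zero_diagonal(self, toy_matrix, toy_catalog):
        inc = build_incidence(toy_matrix, toy_catalog)
        for adj in (node_adjacency(inc), dual_adjacency(inc)):
            np.testing.assert_allclose(adj.values, adj.values.T)
            assert (np.diag(adj.values) == 0).all()
            assert (adj.values >= 0).all()


class TestCentrality:
    def test_two_node_graph_closed_form(self):
        adj = AdjacencyMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), ("a", "b"), "node")
        tab = eigenvector_centrality(adj)
        assert tab.eigenvalue == pytest.approx(1.0)
        np.testing.assert_allclose(tab.centrality, [2 ** -0.5, 2 ** -0.5])

    def test_toy_closed_form(self, toy_matrix, toy_catalog):
        # characteristic polynomial of the (a, a, b) eigenspace:
        # lambda^2 - 1.5 lambda - 0.5 = 0 -> lambda = (1.5 + sqrt(4.25)) / 2
        inc = build_incidence(toy_matrix, toy_catalog)
        tab = eigenvector_centrality(node_adjacency(inc))
        lam = (1.5 + np.sqrt(4.25)) / 2
        assert tab.eigenvalue == pytest.approx(lam, abs=1e-10)
        b = 1 / np.sqrt(2 * lam ** 2 + 1)
        np.testing.assert_allclose(tab.centrality, [lam * b, lam * b, b], atol=1e-10)

    def test_unit_norm_and_nonnegativity(self):
        rng = np.random.default_rng(5)
        for n in (3, 10, 25):
            a = rng.random((n, n))
            a = a + a.T
            np.fill_diagonal(a, 0.0)
            tab = eigenvector_centrality(AdjacencyMatrix(a, tuple(map(str, range(n))), "node"))
            assert abs(np.linalg.norm(tab.centrality) - 1.0) <= 1e-10
            assert (tab.centrality >= 0).all()

    def test_power_iteration_agrees_with_dense(self):
        rng = np.random.default_rng(6)
        for n in (5, 20, 50):
            a = rng.random((n, n))
            a = a + a.T
            np.fill_diagonal(a, 0.0)
            adj = AdjacencyMatrix(a, tuple(map(str, range(n))), "node")
            dense = eigenvector_centrality(adj, method="dense")
            power = eigenvector_centrality(adj, method="power")
            assert np.abs(dense.centrality - power.centrality).max() <= 1e-8
            assert dense.eigenvalue == pytest.approx(power.eigenvalue, abs=1e-8)

    def test_matches_networkx_on_weighted_graph(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(8)
        a = rng.random((12, 12))
        a = a + a.T
        np.fill_diagonal(a, 0.0)
        tab = eigenvector_centrality(AdjacencyMatrix(a, tuple(map(str, range(12))), "node"))
        g = nx.from_numpy_array(a)
        ref = nx.eigenvector_centrality_numpy(g, weight="weight")
        vec = np.abs(np.array([ref[i] for i in range(12)]))
        vec /= np.linalg.norm(vec)
        np.testing.assert_allclose(tab.centrality, vec, atol=1e-8)

    def test_disconnected_graph_uses_dominant_component(self):
        # component {0,1} has eigenvalue 3, component {2,3} eigenvalue 1
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 3.0
        a[2, 3] = a[3, 2] = 1.0
        tab = eigenvector_centrality(AdjacencyMatrix(a, ("a", "b", "c", "d"), "node"))
        assert tab.eigenvalue == pytest.approx(3.0)
        np.testing.assert_allclose(tab.centrality, [2 ** -0.5, 2 ** -0.5, 0.0, 0.0],
                                   atol=1e-12)

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(DegenerateGraphError):
            eigenvector_centrality(AdjacencyMatrix(np.zeros((3, 3)), ("a", "b", "c"), "node"))

    def test_edge_weight_scale_invariance(self, toy_matrix, toy_catalog):
        inc = build_incidence(toy_matrix, toy_catalog)
        base = eigenvector_centrality(node_adjacency(inc))
        scaled_adj = node_adjacency(inc)
        scaled = eigenvector_centrality(
            AdjacencyMatrix(scaled_adj.values * 7.3, scaled_adj.labels, "node"))
        np.testing.assert_allclose(base.centrality, scaled.centrality, atol=1e-10)
        assert scaled.eigenvalue == pytest.approx(base.eigenvalue * 7.3)


class TestRanking:
    def test_descending_ranks(self):
        tab = CentralityTable(("hypertension", "arthritis", "obesity"),
                              np.array([0.5, 0.45, 0.42]), 1.0)
        assert rank_centralities(tab) == [("hypertension", 0.5, 1),
                                          ("arthritis", 0.45, 2),
                                          ("obesity", 0.42, 3)]

    def test_ties_share_lower_rank_in_catalog_order(self):
        tab = CentralityTable(("a", "b", "c"), np.array([0.3, 0.5, 0.5]), 1.0)
        assert rank_centralities(tab) == [("b", 0.5, 1), ("c", 0.5, 1), ("a", 0.3, 3)]

    def test_invariant_to_label_permutation(self):
        vals = np.array([0.2, 0.7, 0.1, 0.7])
        tab = CentralityTable(("w", "x", "y", "z"), vals, 1.0)
        ranks = {lab: r for lab, _, r in rank_centralities(tab)}
        assert ranks == {"x": 1, "z": 1, "w": 3, "y": 4}
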