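"""Force constants, Randic resistance, Kirchhoff/Wiener indices, sum rules."""

import json

import networkx as nx
import numpy as np
import pytest

from pgfold import (
    DisconnectedGraphError,
    Graph,
    compute_descriptor_set,
    global_force_constant,
    laplacian,
    laplacian_pseudoinverse,
    local_force_constants,
    nonlocal_force_constants,
    path_graph,
    randic_resistance,
    shortest_path_stats,
    spectral_decomposition,
)
from pgfold.analytic_models import complete_graph

from conftest import random_connected_graph, random_tree


def spec_of(graph):
    return spectral_decomposition(laplacian(graph))


class TestLocalForceConstants:
    def test_p3_by_hand(self, p3):
        # e2=(1,0,-1)/sqrt2, e3=(1,-2,1)/sqrt6: 1/k1 = 1/2 + 1/18 = 5/9
        np.testing.assert_allclose(
            local_force_constants(spec_of(p3)), [1.8, 4.5, 1.8], atol=1e-12
        )

    def test_k3_uniform(self, k3):
        np.testing.assert_allclose(local_force_constants(spec_of(k3)), 4.5, atol=1e-12)

    def test_equals_inverse_pseudoinverse_diagonal(self, rng):
        for _ in range(10):
            g = random_connected_graph(rng, int(rng.integers(3, 50)))
            k = local_force_constants(spec_of(g))
            pinv = laplacian_pseudoinverse(laplacian(g))
            np.testing.assert_allclose(1.0 / k, np.diagonal(pinv), atol=1e-9)

    def test_symmetry_orbit_equivalence(self, p3):
        k = local_force_constants(spec_of(p3))
        assert k[0] == pytest.approx(k[2], abs=1e-12)

    def test_disconnected_raises(self):
        g = Graph.from_edges(4, [(1, 2), (3, 4)])
        with pytest.raises(DisconnectedGraphError):
            local_force_constants(spec_of(g))


class TestGlobalForceConstant:
    def test_p3(self, p3):
        assert global_force_constant(spec_of(p3)) == pytest.approx(0.75, abs=1e-12)

    def test_path20_minimum_rigidity(self):
        # softest possible 20-residue protein graph
        K = global_force_constant(spec_of(path_graph(20)))
        assert K == pytest.approx(6.0 / 399.0, abs=1e-12)
        assert round(K, 4) == 0.0150

    def test_complete20_maximum_rigidity(self):
        K = global_force_constant(spec_of(complete_graph(20)))
        assert K == pytest.approx(20.0 / 19.0, abs=1e-12)
        assert round(K, 4) == 1.0526

    def test_equals_inverse_trace_of_pseudoinverse(self, rng):
        g = random_connected_graph(rng, 25)
        K = global_force_constant(spec_of(g))
        assert 1.0 / K == pytest.approx(
            np.trace(laplacian_pseudoinverse(laplacian(g))), abs=1e-9
        )


class TestNonlocalAndResistance:
    def test_p2_pair_constant(self, p2):
        K = nonlocal_force_constants(spec_of(p2))
        assert K[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert np.isinf(K[0, 0])

    def test_p3_series_springs(self, p3):
        K = nonlocal_force_constants(spec_of(p3))
        assert 1.0 / K[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert 1.0 / K[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_p3_resistances_series_law(self, p3):
        omega = randic_resistance(laplacian_pseudoinverse(laplacian(p3)))
        expected = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        np.testing.assert_allclose(omega, expected, atol=1e-12)

    def test_k3_resistances(self, k3):
        omega = randic_resistance(laplacian_pseudoinverse(laplacian(k3)))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(omega[off], 2.0 / 3.0, atol=1e-12)

    def test_resistance_is_inverse_nonlocal_constant(self, rng):
        for _ in range(5):
            g = random_connected_graph(rng, int(rng.integers(3, 40)))
            K = nonlocal_force_constants(spec_of(g))
            omega = randic_resistance(laplacian_pseudoinverse(laplacian(g)))
            off = ~np.eye(g.n, dtype=bool)
            np.testing.assert_allclose(omega[off], 1.0 / K[off], atol=1e-9)

    def test_tree_resistance_equals_path_distance(self, rng):
        for _ in range(8):
            tree = random_tree(rng, int(rng.integers(3, 30)))
            omega = randic_resistance(laplacian_pseudoinverse(laplacian(tree)))
            from pgfold.descriptors import shortest_path_matrix

            np.testing.assert_allclose(omega, shortest_path_matrix(tree), atol=1e-8)


class TestShortestPaths:
    def test_p3_mean(self, p3):
        wiener, l0 = shortest_path_stats(p3)
        assert l0 == pytest.approx(4.0 / 3.0, abs=1e-12)
        assert wiener == 8.0  # ordered pairs: 2*(1+2+1)

    def test_path20_fully_unfolded(self):
        _, l0 = shortest_path_stats(path_graph(20))
        assert l0 == pytest.approx(7.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_complete_graph_unit_paths(self, n):
        _, l0 = shortest_path_stats(complete_graph(n))
        assert l0 == 1.0

    def test_wiener_even_integer_for_unweighted(self, rng):
        for _ in range(5):
            g = random_connected_graph(rng, int(rng.integers(3, 30)))
            wiener, _ = shortest_path_stats(g)
            assert wiener == int(wiener) and int(wiener) % 2 == 0

    def test_matches_networkx_mean(self, rng):
        # independent route: networkx BFS average over the same graph
        for _ in range(5):
            g = random_connected_graph(rng, int(rng.integers(4, 30)))
            _, l0 = shortest_path_stats(g)
            gx = nx.from_numpy_array(g.weights)
            assert l0 == pytest.approx(nx.average_shortest_path_length(gx), abs=1e-10)

    def test_weighted_dijkstra_route(self):
        g = Graph.from_edges(3, [(1, 2, 2.0), (2, 3, 3.0), (1, 3, 10.0)])
        from pgfold.descriptors import shortest_path_matrix

        dist = shortest_path_matrix(g)
        assert dist[0, 2] == pytest.approx(5.0)

    def test_disconnected_raises(self):
        with pytest.raises(DisconnectedGraphError):
            shortest_path_stats(Graph.from_edges(4, [(1, 2), (3, 4)]))


class TestSumRules:
    def test_sum_rules_on_random_graphs(self, rng):
        """The three identities tying local, nonlocal and global constants."""
        for _ in range(200):
            g = random_connected_graph(rng, int(rng.integers(3, 51)))
            spec = spec_of(g)
            k = local_force_constants(spec)
            K = global_force_constant(spec)
            Knl = nonlocal_force_constants(spec)
            inv_Knl = 1.0 / Knl
            np.fill_diagonal(inv_Knl, 0.0)
            # 1/K = (1/2n) sum_ij 1/K_ij
            assert 1.0 / K == pytest.approx(inv_Knl.sum() / (2 * g.n), abs=1e-8)
            # 1/K = sum_i 1/k_i
            assert 1.0 / K == pytest.approx(np.sum(1.0 / k), abs=1e-8)
            # 1/k_i = (1/n)(sum_j 1/K_ij - 1/K)
            np.testing.assert_allclose(
                1.0 / k, (inv_Knl.sum(axis=1) - 1.0 / K) / g.n, atol=1e-8
            )


class TestRayleighMonotonicity:
    def test_adding_edge_stiffens_and_shortens(self, rng):
        for _ in range(20):
            g = random_connected_graph(rng, int(rng.integers(4, 25)), p=0.2)
            zeros = np.argwhere(np.triu(g.weights == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w = g.weights.copy()
            w[i, j] = w[j, i] = 1.0
            denser = Graph(w)
            assert global_force_constant(spec_of(denser)) >= global_force_constant(
                spec_of(g)
            ) - 1e-12
            assert shortest_path_stats(denser)[1] <= shortest_path_stats(g)[1] + 1e-12


class TestDescriptorSet:
    def test_p3_record(self, p3):
        d = compute_descriptor_set(p3)
        assert d.K_global == pytest.approx(0.75, abs=1e-12)
        assert d.kirchhoff == pytest.approx(4.0 / 3.0, abs=1e-12)
        np.testing.assert_allclose(d.k_local, [1.8, 4.5, 1.8], atol=1e-12)
        assert d.l0_mean == pytest.approx(4.0 / 3.0, abs=1e-12)
        np.testing.assert_allclose(d.degrees, [1, 2, 1])

    def test_internal_identities(self, rng):
        g = random_connected_graph(rng, 30)
        d = compute_descriptor_set(g)
        off = ~np.eye(d.n, dtype=bool)
        np.testing.assert_allclose(d.randic[off], 1.0 / d.K_nonlocal[off], rtol=1e-8)
        assert np.sum(1.0 / d.k_local) == pytest.approx(d.kirchhoff, rel=1e-8)
        assert np.all(d.k_local > 0)
        assert np.all(np.isinf(np.diagonal(d.K_nonlocal)))

    def test_json_and_csv_writers(self, tmp_path, p3):
        d = compute_descriptor_set(p3)
        obj = json.loads(d.to_json())
        assert obj["n"] == 3 and obj["K_global"] == pytest.approx(0.75)
        out = tmp_path / "desc.csv"
        d.to_csv(out, matrices=True)
        text = out.read_text()
        assert "vertex,degree,k_local" in text and "# randic_resistance_matrix" in text
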