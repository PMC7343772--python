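"""The nine weighted graph measures: hand-computed cases, invariances and
independent cross-checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_graph
from dynconn.graphmetrics import (
    METRIC_ORDER,
    avg_neighbor_degree,
    characteristic_path_length,
    clustering_coefficient,
    efficiency_complexity,
    global_efficiency,
    graph_density,
    graph_index_complexity,
    metric_vector,
    shannon_graph_complexity,
    small_world,
)


def triangle(w01, w02, w12):
    return np.array([[0, w01, w02], [w01, 0, w12], [w02, w12, 0]], dtype=float)


def unit_complete(n):
    return np.ones((n, n)) - np.eye(n)


def unit_path(n):
    w = np.zeros((n, n))
    for i in range(n - 1):
        w[i, i + 1] = w[i + 1, i] = 1.0
    return w


class TestDensityAndEntropy:
    def test_unit_k3_density_is_one(self):
        assert graph_density(unit_complete(3)) == pytest.approx(1.0)

    def test_density_is_mean_offdiagonal_weight(self):
        assert graph_density(triangle(0.2, 0.4, 0.6)) == pytest.approx(0.4)

    def test_all_zero_density_is_zero(self):
        assert graph_density(np.zeros((4, 4))) == pytest.approx(0.0)

    def test_uniform_weights_have_maximal_entropy(self):
        assert shannon_graph_complexity(0.3 * unit_complete(5)) == pytest.approx(1.0)

    def test_single_edge_has_zero_entropy(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.7
        assert shannon_graph_complexity(w) == pytest.approx(0.0)

    def test_hand_entropy(self):
        # p = {0.5, 0.25, 0.25}: H = 1.5 bits, M = 3 edges
        w = triangle(0.5, 0.25, 0.25)
        assert shannon_graph_complexity(w) == pytest.approx(1.5 / np.log2(3))

    def test_all_zero_entropy_rejected(self):
        with pytest.raises(ValueError):
            shannon_graph_complexity(np.zeros((3, 3)))


class TestGraphIndexComplexity:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_path_and_complete_graphs_score_zero(self, n):
        assert graph_index_complexity(unit_path(n)) == pytest.approx(0.0, abs=1e-9)
        assert graph_index_complexity(unit_complete(n)) == pytest.approx(0.0, abs=1e-9)

    def test_midpoint_eigenvalue_scores_one(self):
        # uniform complete graph with lambda_max halfway between the references
        n = 6
        low = 2 * np.cos(np.pi / (n + 1))
        alpha = (low + (n - 1)) / 2 / (n - 1)
        assert graph_index_complexity(alpha * unit_complete(n)) == pytest.approx(1.0)


class TestNeighborDegree:
    def test_single_edge_value_is_the_weight(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.6
        assert avg_neighbor_degree(w) == pytest.approx(0.6)

    def test_unit_k3_value_is_two(self):
        assert avg_neighbor_degree(unit_complete(3)) == pytest.approx(2.0)

    def test_degree_one_homogeneity(self):
        w = random_graph(6, np.random.default_rng(0))
        assert avg_neighbor_degree(3.0 * w) == pytest.approx(3.0 * avg_neighbor_degree(w))

    def test_matches_independent_loop_implementation(self):
        w = random_graph(7, np.random.default_rng(1), zero_frac=0.3)
        s = w.sum(axis=1)
        vals = [
            sum(w[i, j] * s[j] for j in range(7)) / s[i] for i in range(7) if s[i] > 0
        ]
        assert avg_neighbor_degree(w) == pytest.approx(np.mean(vals))

    def test_all_isolated_rejected(self):
        with pytest.raises(ValueError):
            avg_neighbor_degree(np.zeros((3, 3)))


class TestEfficiency:
    def test_unit_complete_graph_efficiency_is_one(self):
        assert global_efficiency(unit_complete(5)) == pytest.approx(1.0)

    def test_two_nodes_half_weight(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        assert global_efficiency(w) == pytest.approx(0.5)

    def test_isolated_node_contributes_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        assert global_efficiency(w) == pytest.approx(1.0 / 3.0)

    def test_efficiency_complexity_extremes_are_zero(self):
        assert efficiency_complexity(unit_complete(6)) == pytest.approx(0.0)
        assert efficiency_complexity(unit_path(6)) == pytest.approx(0.0, abs=1e-9)

    def test_efficiency_complexity_vertex(self):
        # uniform complete graph with Ge halfway between path and complete refs
        n = 5
        lo = global_efficiency(unit_path(n))
        alpha = (lo + 1.0) / 2.0
        assert efficiency_complexity(alpha * unit_complete(n)) == pytest.approx(1.0)


class TestClusteringAndPathLength:
    def test_unit_triangle_fully_clustered(self):
        assert clustering_coefficient(unit_complete(3)) == pytest.approx(1.0)

    def test_open_triangle_has_no_clustering(self):
        assert clustering_coefficient(triangle(1.0, 1.0, 0.0)) == pytest.approx(0.0)

    def test_geometric_mean_weights(self):
        # node 0 joins the two unit edges; its triangle intensity is 0.125^(1/3)
        w = triangle(1.0, 1.0, 0.125)
        a = (1.0 * 1.0 * 0.125) ** (1.0 / 3.0)
        assert clustering_coefficient(w) == pytest.approx(a)  # all three nodes equal here

    def test_matches_networkx_onnela(self):
        nx = pytest.importorskip("networkx")
        w = random_graph(7, np.random.default_rng(2), zero_frac=0.2)
        g = nx.from_numpy_array(w)
        assert clustering_coefficient(w) == pytest.approx(nx.average_clustering(g, weight="weight"))

    def test_unit_chain_path_length(self):
        assert characteristic_path_length(unit_path(3)) == pytest.approx(4.0 / 3.0)

    def test_halving_weights_doubles_path_length(self):
        w = random_graph(6, np.random.default_rng(3))
        assert characteristic_path_length(0.5 * w) == pytest.approx(
            2.0 * characteristic_path_length(w)
        )

    def test_disconnected_pairs_excluded_with_warning(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        with pytest.warns(RuntimeWarning):
            assert characteristic_path_length(w) == pytest.approx(1.0)


class TestSmallWorld:
    def test_equal_weight_complete_graph_scores_exactly_one(self):
        assert small_world(0.4 * unit_complete(6), n_surrogates=5, seed=0) == pytest.approx(1.0)

    def test_seeded_determinism(self):
        w = random_graph(8, np.random.default_rng(4))
        assert small_world(w, 20, seed=5) == small_world(w, 20, seed=5)

    def test_lattice_with_shortcuts_beats_its_shuffle(self):
        # weighted ring lattice (strong local edges) plus two strong shortcuts
        n = 12
        w = np.zeros((n, n))
        for i in range(n):
            w[i, (i + 1) % n] = w[(i + 1) % n, i] = 1.0
            w[i, (i + 2) % n] = w[(i + 2) % n, i] = 0.6
        w[0, 6] = w[6, 0] = 1.0
        w[3, 9] = w[9, 3] = 1.0
        rng = np.random.default_rng(6)
        iu = np.triu_indices(n, 1)
        shuffled = np.zeros_like(w)
        shuffled[iu] = rng.permutation(w[iu])
        shuffled = shuffled + shuffled.T
        assert small_world(w, 20, seed=7) > small_world(shuffled, 20, seed=7)

    def test_degenerate_surrogates_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0  # surrogates can disconnect a 3-node single-edge graph
        with pytest.raises(ValueError):
            small_world(w, n_surrogates=1, seed=1)


class TestMetricVector:
    def test_unit_k3_vector(self):
        mv = metric_vector(unit_complete(3))
        assert mv.as_array() == pytest.approx([0, 1, 1, 2, 0, 1, 1, 1, 1], abs=1e-9)

    def test_vector_has_nine_entries_in_fixed_order(self):
        mv = metric_vector(random_graph(5, np.random.default_rng(7)))
        assert len(mv.as_array()) == 9
        assert tuple(mv.as_dict()) == METRIC_ORDER

    @given(st.integers(0, 1000))
    def test_label_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        w = random_graph(6, rng, zero_frac=0.2)
        if w.sum() == 0 or (w.sum(axis=1) == 0).any():
            return
        perm = rng.permutation(6)
        wp = w[np.ix_(perm, perm)]
        np.testing.assert_allclose(
            metric_vector(w, sw_surrogates=5, seed=3).as_array(),
            metric_vector(wp, sw_surrogates=5, seed=3).as_array(),
            rtol=1e-9,
        )

    def test_bounds_hold_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            n = rng.integers(3, 9)
            w = random_graph(int(n), rng, zero_frac=float(rng.uniform(0, 0.3)))
            if (w.sum(axis=1) == 0).any() or w.max() == 0:
                continue
            try:
                mv = metric_vector(w, sw_surrogates=3, seed=1)
            except ValueError:
                continue  # triangle-free draws make SW legitimately degenerate

            for name in ("Cr", "GD", "SGC", "Ce", "Ge", "C"):
                v = getattr(mv, name)
                assert 0.0 <= v <= 1.0 + 1e-9, name
            assert mv.K >= 0 and mv.L >= 0
            # SW is strictly positive whenever the graph itself clusters;
            # a triangle-free graph scores exactly 0
            assert mv.SW > 0 if mv.C > 0 else mv.SW == 0

    def test_asymmetric_or_negative_matrices_rejected(self):
        with pytest.raises(ValueError):
            metric_vector(np.array([[0.0, 1.0], [0.5, 0.0]]))
        with pytest.raises(ValueError):
            metric_vector(np.array([[0.0, -1.0], [-1.0, 0.0]]))
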