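"""Binarization, hypergeometric Surprise, greedy detection, threshold sweep."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nclnet import (
    BinaryGraph,
    DataError,
    ParameterError,
    Partition,
    binarize,
    detect_communities_surprise,
    percolation_profile,
    select_optimal_threshold,
    surprise_of_partition,
)
from nclnet.surprise import threshold_grid

from _oracles import best_partition, exact_surprise, random_graph
from conftest import make_tensor


def _graph(edges, n):
    adj = np.zeros((n, n), dtype=np.uint8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adjacency=adj)


TRIANGLE_PLUS_ISOLATE = _graph([(0, 1), (0, 2), (1, 2)], 4)
TWO_TRIANGLES = _graph([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)], 6)


class TestBinarize:
    def test_low_threshold_complete(self):
        g = binarize(np.full((5, 5), 0.9), 0.0)
        assert g.m == 10

    def test_threshold_one_empty(self):
        g = binarize(np.ones((5, 5)), 1.0)  # strict >
        assert g.m == 0

    def test_hand_case(self):
        w = np.full((4, 4), 0.2)
        for (i, j), v in {(1, 2): 0.8, (1, 3): 0.6, (2, 3): 0.7}.items():
            w[i, j] = w[j, i] = v
        g = binarize(w, 0.5)
        assert g.m == 3
        assert g.adjacency[1, 2] and g.adjacency[1, 3] and g.adjacency[2, 3]
        assert g.adjacency[0].sum() == 0

    def test_asymmetric_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        with pytest.raises(DataError):
            binarize(w, 0.2)

    @given(tau1=st.floats(0, 1), tau2=st.floats(0, 1), seed=st.integers(0, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_edge_sets(self, tau1, tau2, seed):
        if tau1 > tau2:
            tau1, tau2 = tau2, tau1
        rng = np.random.default_rng(seed)
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        sparse = binarize(w, tau2).adjacency
        dense = binarize(w, tau1).adjacency
        assert np.all(sparse <= dense)


class TestSurpriseValue:
    def test_all_in_one_is_zero(self):
        assert surprise_of_partition(TWO_TRIANGLES, Partition((0,) * 6)) == 0.0

    def test_all_singletons_is_zero(self):
        assert surprise_of_partition(TWO_TRIANGLES, Partition(tuple(range(6)))) == 0.0

    def test_triangle_plus_isolate_worked_example(self):
        s = surprise_of_partition(TRIANGLE_PLUS_ISOLATE, Partition((0, 0, 0, 1)))
        assert s == pytest.approx(-np.log10(0.05), abs=1e-9)  # 1.30103

    def test_empty_graph_zero_by_convention(self):
        g = _graph([], 4)
        assert surprise_of_partition(g, Partition((0, 0, 1, 1))) == 0.0

    def test_matches_exact_oracle_on_random_partitions(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            adj = random_graph(rng, n, 0.5)
            labels = rng.integers(0, 3, size=n)
            g = BinaryGraph(adjacency=adj)
            s_impl = surprise_of_partition(g, Partition(tuple(labels)))
            s_exact = exact_surprise(adj, labels)
            assert s_impl == pytest.approx(s_exact, abs=1e-9)

    def test_nonnegative_on_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            adj = random_graph(rng, n, rng.uniform(0.2, 0.9))
            labels = rng.integers(0, n, size=n)
            assert surprise_of_partition(BinaryGraph(adjacency=adj), Partition(tuple(labels))) >= 0.0


class TestDetectSurprise:
    def test_two_triangles_recovered(self):
        part = detect_communities_surprise(TWO_TRIANGLES, seed=0)
        labels = np.asarray(part.labels)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]

    def test_complete_graph_surprise_zero(self):
        g = _graph([(i, j) for i in range(5) for j in range(i + 1, 5)], 5)
        part = detect_communities_surprise(g, seed=0)
        assert surprise_of_partition(g, part) == 0.0

    def test_reaches_exhaustive_maximum_usually_never_above(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_graphs = 20
        for _ in range(n_graphs):
            n = int(rng.integers(5, 9))
            adj = random_graph(rng, n, rng.uniform(0.3, 0.7))
            g = BinaryGraph(adjacency=adj)
            part = detect_communities_surprise(g, seed=0)
            s_greedy = surprise_of_partition(g, part)
            s_max, _ = best_partition(adj, exact_surprise)
            assert s_greedy <= s_max + 1e-9
            if abs(s_greedy - s_max) < 1e-9:
                hits += 1
        assert hits >= 0.8 * n_graphs

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        adj = random_graph(rng, 12, 0.4)
        g = BinaryGraph(adjacency=adj)
        assert detect_communities_surprise(g, seed=5) == detect_communities_surprise(g, seed=5)


class TestPercolation:
    def test_below_min_weight_fully_connected(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.4, 0.9, (6, 6))
        w = (w + w.T) / 2
        frac = percolation_profile(w, np.array([0.1]))
        assert frac[0] == 1.0

    def test_above_max_weight_all_isolates(self):
        rng = np.random.default_rng(0)
        w = rng.uniform(0.1, 0.5, (8, 8))
        w = (w + w.T) / 2
        frac = percolation_profile(w, np.array([0.99]))
        assert frac[0] == pytest.approx(1 / 8)

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            w = rng.random((10, 10))
            w = (w + w.T) / 2
            frac = percolation_profile(w, threshold_grid(50))
            assert np.all(np.diff(frac) <= 1e-12)

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            percolation_profile(np.zeros((3, 3)), np.array([0.5, 0.2]))


class TestSelectOptimal:
    def test_all_ones_ties_break_to_smallest(self):
        t = make_tensor(np.ones((2, 3, 6, 6)))
        sweep = select_optimal_threshold([t], grid_size=100)
        assert sweep.optimal == pytest.approx(1 / 101)

    def test_planted_two_module_structure(self):
        """Only thresholds inside the weight gap separate the two modules."""
        n = 10
        w = np.full((n, n), 0.3)
        w[:5, :5] = 0.8
        w[5:, 5:] = 0.8
        np.fill_diagonal(w, 1.0)
        vals = np.tile(w, (3, 4, 1, 1))
        sweep = select_optimal_threshold([make_tensor(vals)], grid_size=100)
        assert 0.3 < sweep.optimal < 0.8

    def test_argmax_contract(self):
        t = make_tensor(np.random.default_rng(0).uniform(0.2, 0.9, (3, 3, 8, 8)))
        vals = 0.5 * (t.values + np.swapaxes(t.values, -1, -2))
        t.values = vals
        sweep = select_optimal_threshold([t], grid_size=50)
        assert sweep.optimal == sweep.thresholds[np.argmax(sweep.mean_surprise)]
        assert np.all(sweep.mean_surprise >= 0.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.1, 0.9, (4, 2, 6, 6))
        vals = 0.5 * (vals + np.swapaxes(vals, -1, -2))
        a = make_tensor(vals, subject_id="bird0")
        b = make_tensor(vals[::-1].copy(), subject_id="bird1")
        s1 = select_optimal_threshold([a, b], grid_size=40)
        s2 = select_optimal_threshold([b, a], grid_size=40)
        np.testing.assert_allclose(s1.mean_surprise, s2.mean_surprise, atol=1e-12)
        assert s1.optimal == s2.optimal

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            select_optimal_threshold([])

    def test_mixed_bands_rejected(self):
        a = make_tensor(np.ones((1, 3, 4, 4)), band_name="beta")
        b = make_tensor(np.ones((1, 3, 4, 4)), band_name="theta")
        with pytest.raises(ParameterError):
            select_optimal_threshold([a, b])
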