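import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pleiomap as pm
from pleiomap.exceptions import DegenerateDistanceError, FragmentedDataError
from pleiomap.phenomap import EmbeddingConfig, TransformedDistances


def symmetric(off_diag: dict[tuple[int, int], float], k: int) -> np.ndarray:
    mat = np.zeros((k, k))
    for (i, j), v in off_diag.items():
        mat[i, j] = mat[j, i] = v
    return mat


def td_from(dist: np.ndarray, lam: float = 0.0) -> TransformedDistances:
    return TransformedDistances(dist=dist, lam=lam, raw_range=(0.0, 1.0))


def brute_force_shortest_paths(graph: nx.Graph) -> np.ndarray:
    """Exhaustive enumeration of all simple paths (independent oracle)."""
    nodes = sorted(graph.nodes())
    k = len(nodes)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            best = np.inf
            for path in nx.all_simple_paths(graph, nodes[a], nodes[b]):
                length = sum(
                    graph[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
                )
                best = min(best, length)
            out[a, b] = out[b, a] = best
    return out


class TestBoxCox:
    def test_lambda_one(self):
        assert pm.box_cox(0.3, 1.0) == pytest.approx(-0.7)

    def test_lambda_zero_at_one(self):
        assert pm.box_cox(1.0, 0.0) == pytest.approx(0.0)

    def test_lambda_half(self):
        assert pm.box_cox(0.25, 0.5) == pytest.approx(-1.0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            pm.box_cox(0.0, 0.5)
        with pytest.raises(ValueError):
            pm.box_cox(-0.5, 0.5)

    @given(
        y1=st.floats(min_value=1e-10, max_value=1.0),
        y2=st.floats(min_value=1e-10, max_value=1.0),
        lam=st.floats(min_value=-2.0, max_value=2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing(self, y1, y2, lam):
        if y1 == y2:
            assert pm.box_cox(y1, lam) == pm.box_cox(y2, lam)
        else:
            lo, hi = sorted((y1, y2))
            assert pm.box_cox(lo, lam) <= pm.box_cox(hi, lam)

    @given(y=st.floats(min_value=1e-6, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_continuity_at_zero(self, y):
        assert abs(pm.box_cox(y, 1e-8) - np.log(y)) < 1e-6


class TestTransformDistanceMatrix:
    y3 = symmetric({(0, 1): 0.001, (0, 2): 0.01, (1, 2): 0.5}, 3)

    def _fix_diag(self, mat):
        mat = mat.copy()
        np.fill_diagonal(mat, 1.0)
        return mat

    def test_normalization_bounds(self):
        td = pm.transform_distance_matrix(self._fix_diag(self.y3), lam=0.0)
        off = td.dist[~np.eye(3, dtype=bool)]
        assert off.min() == pytest.approx(0.0)
        assert off.max() == pytest.approx(1.0)
        np.testing.assert_array_equal(np.diag(td.dist), 0.0)

    def test_rank_preserved(self):
        rng = np.random.default_rng(50)
        vals = rng.random(6) * 0.9 + 0.05
        raw = symmetric(
            dict(zip(itertools.combinations(range(4), 2), vals)), 4
        )
        mat = self._fix_diag(raw)
        for lam in (-1.0, 0.0, 0.5, 1.0):
            td = pm.transform_distance_matrix(mat, lam)
            iu = np.triu_indices(4, k=1)
            assert np.array_equal(
                np.argsort(td.dist[iu]), np.argsort(raw[iu])
            )

    def test_lambda_zoom_hand_values(self):
        # off-diagonal p-values (0.001, 0.01, 0.5): normalized distance of
        # the intermediate pair, hand-computed per lambda
        expected = {1.0: 0.018036, 0.5: 0.101221, 0.0: 0.370513, -1.0: 0.901804}
        mat = self._fix_diag(self.y3)
        for lam, value in expected.items():
            td = pm.transform_distance_matrix(mat, lam)
            assert td.dist[0, 2] == pytest.approx(value, abs=1e-5)

    def test_smaller_lambda_expands_small_pvalues(self):
        # decreasing lambda never decreases the normalized distance of the
        # intermediate pairs (zoom-out stretches strong pleiotropy signals)
        mat = self._fix_diag(
            symmetric(
                {(0, 1): 1e-4, (0, 2): 1e-3, (0, 3): 0.05,
                 (1, 2): 0.2, (1, 3): 0.5, (2, 3): 0.9},
                4,
            )
        )
        prev = None
        for lam in (1.0, 0.5, 0.0, -0.5, -1.0):
            td = pm.transform_distance_matrix(mat, lam)
            if prev is not None:
                assert np.all(td.dist >= prev - 1e-12)
            prev = td.dist

    def test_degenerate_rejected(self):
        mat = self._fix_diag(symmetric(
            {(0, 1): 0.5, (0, 2): 0.5, (1, 2): 0.5}, 3
        ))
        with pytest.raises(DegenerateDistanceError):
            pm.transform_distance_matrix(mat, 0.0)

    def test_pleiotropy_matrix_input_uses_log_pvalues(self, scenario_pipelines):
        mat = scenario_pipelines["A"][0].pleiotropy
        td = pm.transform_distance_matrix(mat, lam=0.0)
        assert td.phenotype_names == mat.phenotype_names
        iu = np.triu_indices(5, k=1)
        assert np.array_equal(
            np.argsort(td.dist[iu]), np.argsort(mat.log_pvalues[iu])
        )

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            pm.transform_distance_matrix(np.array([[1.0, 0.5], [0.5, 1.0]]), 0.0)


CHAIN = symmetric(
    {(0, 1): 0.1, (1, 2): 0.1, (2, 3): 0.1,
     (0, 2): 0.9, (0, 3): 0.9, (1, 3): 0.9},
    4,
)


class TestEpsilonGraph:
    def test_complete_at_one(self):
        td = td_from(CHAIN)
        g = pm.epsilon_graph(td, 1.0)
        assert g.number_of_edges() == 6

    def test_fragmented_below_minimum(self):
        td = td_from(CHAIN)
        with pytest.raises(FragmentedDataError):
            pm.epsilon_graph(td, 0.05)

    def test_chain_is_path_graph(self):
        g = pm.epsilon_graph(td_from(CHAIN), 0.15)
        assert sorted(g.edges()) == [(0, 1), (1, 2), (2, 3)]

    def test_invalid_epsilon(self):
        with pytest.raises(ValueError):
            pm.epsilon_graph(td_from(CHAIN), 0.0)


class TestShortestPaths:
    def test_triangle_inequality_input_unchanged(self):
        mat = symmetric({(0, 1): 1.0, (0, 2): 1.5, (1, 2): 1.0}, 3)
        g = nx.Graph()
        for i in range(3):
            for j in range(i + 1, 3):
                g.add_edge(i, j, weight=mat[i, j])
        np.testing.assert_allclose(pm.shortest_path_distances(g), mat)

    def test_two_hop_path(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        d = pm.shortest_path_distances(g)
        assert d[0, 2] == pytest.approx(2.0)  # nodes sorted: A, B, C

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(51)
        for trial in range(5):
            g = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(1 << 30)))
            while not nx.is_connected(g):
                g = nx.gnp_random_graph(6, 0.6, seed=int(rng.integers(1 << 30)))
            for u, v in g.edges():
                g[u][v]["weight"] = float(rng.random() + 0.01)
            np.testing.assert_allclose(
                pm.shortest_path_distances(g), brute_force_shortest_paths(g),
                atol=1e-12,
            )

    def test_disconnected_rejected(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        with pytest.raises(FragmentedDataError):
            pm.shortest_path_distances(g)

    def test_properties(self):
        g = nx.gnp_random_graph(6, 0.7, seed=3)
        for u, v in g.edges():
            g[u][v]["weight"] = 0.5
        d = pm.shortest_path_distances(g)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0.0)
        # triangle inequality
        k = d.shape[0]
        for a, b, c in itertools.permutations(range(k), 3):
            assert d[a, b] <= d[a, c] + d[c, b] + 1e-12


class TestClassicalMds:
    def test_equilateral_triangle(self):
        d = symmetric({(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0}, 3)
        coords, eigvals = pm.classical_mds(d, 2)
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(got, d, atol=1e-9)
        assert eigvals[0] >= eigvals[1] > 0

    def test_collinear_points(self):
        d = symmetric({(0, 1): 1.0, (1, 2): 2.0, (0, 2): 3.0}, 3)
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            coords, _ = pm.classical_mds(d, 2)
        np.testing.assert_allclose(coords[:, 1], 0.0, atol=1e-9)
        gaps = np.abs(np.diff(coords[:, 0]))
        np.testing.assert_allclose(sorted(gaps), [1.0, 2.0], atol=1e-9)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(52)
        pts = rng.random((5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = pm.classical_mds(d, 2)
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(got, d, atol=1e-8)

    def test_coordinates_centered(self):
        rng = np.random.default_rng(53)
        pts = rng.random((6, 2)) * 4
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = pm.classical_mds(d, 2)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_sign_convention(self):
        rng = np.random.default_rng(54)
        pts = rng.random((5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords, _ = pm.classical_mds(d, 2)
        for axis in coords.T:
            assert axis[np.argmax(np.abs(axis))] >= 0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pm.classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)
        with pytest.raises(ValueError):
            pm.classical_mds(np.array([[0.0, -1.0], [-1.0, 0.0]]), 1)


class TestIsomapEmbed:
    def test_complete_graph_equals_classical_mds(self):
        rng = np.random.default_rng(55)
        pts = rng.random((6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = d / d.max()
        td = td_from(d)
        pmap = pm.isomap_embed(td, EmbeddingConfig(epsilon=1.0, ndim=2))
        coords, eigvals = pm.classical_mds(d, 2)
        np.testing.assert_allclose(pmap.coords, coords, atol=1e-10)
        np.testing.assert_allclose(pmap.eigenvalues, eigvals, atol=1e-10)

    def test_fragmented_propagates(self):
        with pytest.raises(FragmentedDataError):
            pm.isomap_embed(td_from(CHAIN), EmbeddingConfig(epsilon=0.05))

    def test_eigenvalues_sorted(self, scenario_pipelines):
        run = scenario_pipelines["A"][0]
        td = pm.transform_distance_matrix(run.pleiotropy, lam=0.0)
        pmap = pm.isomap_embed(td, EmbeddingConfig(epsilon=None, ndim=2))
        assert pmap.eigenvalues[0] >= pmap.eigenvalues[1]
        np.testing.assert_allclose(pmap.coords.mean(axis=0), 0.0, atol=1e-9)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(56)
        pts = rng.random((5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = d / d.max()
        perm = np.array([3, 0, 4, 1, 2])
        cfg = EmbeddingConfig(epsilon=1.0, ndim=2)
        coords = pm.isomap_embed(td_from(d), cfg).coords
        coords_perm = pm.isomap_embed(td_from(d[np.ix_(perm, perm)]), cfg).coords
        np.testing.assert_allclose(coords_perm, coords[perm], atol=1e-9)

    def test_geodesics_stored(self):
        g_dist = pm.isomap_embed(td_from(CHAIN), EmbeddingConfig(epsilon=0.15))
        assert g_dist.graph_distances[0, 3] == pytest.approx(0.3)


class TestAutoEpsilon:
    def test_small_distances(self):
        d = symmetric({(0, 1): 0.05, (0, 2): 0.08, (1, 2): 0.1}, 3)
        eps = pm.auto_epsilon(td_from(d), grid_step=0.05)
        assert eps in (0.05, 0.1)
        pm.epsilon_graph(td_from(d), eps)  # connects

    def test_chain_rounds_up(self):
        assert pm.auto_epsilon(td_from(CHAIN), grid_step=0.05) == pytest.approx(0.1)

    def test_minimality_on_grid(self):
        rng = np.random.default_rng(57)
        d = rng.random((6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        d = d / d.max()
        td = td_from(d)
        eps = pm.auto_epsilon(td, grid_step=0.05)
        pm.epsilon_graph(td, eps)
        if eps > 0.05:
            with pytest.raises(FragmentedDataError):
                pm.epsilon_graph(td, eps - 0.05)

    def test_invalid_grid(self):
        with pytest.raises(ValueError):
            pm.auto_epsilon(td_from(CHAIN), grid_step=0.0)
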