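import numpy as np
import pytest

from gradscape import resistance as res
from gradscape.raster import Raster
from gradscape.sites import SiteSet


def graph_from(vals, connectivity=8, mask=None):
    cond = Raster(np.asarray(vals, dtype=float), cell_size=1.0, mask=mask)
    return res.build_graph(cond, connectivity=connectivity)


def commute_oracle(graph, i, j):
    """First-step-analysis oracle: solve the hitting-time linear system."""
    adj = graph.adjacency().toarray()
    deg = adj.sum(axis=1)
    P = adj / deg[:, None]
    n = len(deg)

    def hitting(target):
        keep = [k for k in range(n) if k != target]
        A = np.eye(n - 1) - P[np.ix_(keep, keep)]
        h = np.linalg.solve(A, np.ones(n - 1))
        full = np.zeros(n)
        full[keep] = h
        return full

    return hitting(j)[i] + hitting(i)[j]


class TestConductance:
    @pytest.mark.parametrize("h,c", [(0.0, 1.0), (1.0, 2.0), (0.5, 1.125)])
    def test_cubic_transform(self, h, c):
        r = Raster(np.full((3, 3), h), cell_size=1.0)
        assert res.conductance(r).values[1, 1] == pytest.approx(c)

    def test_mask_preserved(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        r = Raster(np.full((3, 3), 0.5), cell_size=1.0, mask=mask)
        out = res.conductance(r)
        assert out.mask[0, 0]

    def test_out_of_range_rejected(self):
        r = Raster(np.full((3, 3), 1.5), cell_size=1.0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            res.conductance(r)


class TestBuildGraph:
    def test_adjacent_edge_mean(self):
        mask = np.ones((2, 2), dtype=bool)
        mask[0, :] = False  # two adjacent cells in the top row
        g = graph_from([[1.0, 2.0], [0.0, 0.0]], connectivity=4, mask=mask)
        assert g.edges.shape == (1, 2)
        assert g.conductances[0] == pytest.approx(1.5)

    def test_diagonal_geo_correction(self):
        mask = np.array([[False, True], [True, False]])
        g = graph_from([[2.0, 0.0], [0.0, 2.0]], connectivity=8, mask=mask)
        assert g.conductances[0] == pytest.approx(2.0 / np.sqrt(2.0))

    @pytest.mark.parametrize("n,connectivity", [(4, 4), (5, 8)])
    def test_edge_count_closed_form(self, n, connectivity):
        g = graph_from(np.ones((n, n)), connectivity=connectivity)
        rook = 2 * n * (n - 1)
        queen = rook + 2 * (n - 1) ** 2
        assert len(g.conductances) == (rook if connectivity == 4 else queen)


class TestLcp:
    def test_uniform_line(self):
        mask = np.ones((3, 5), dtype=bool)
        mask[1, :] = False  # straight line of 5 cells
        g = graph_from(np.where(~mask, 1.0, 0.0), connectivity=4, mask=mask)
        i = g.node_of_cell[1, 0]
        j = g.node_of_cell[1, 4]
        assert res.lcp_distance(g, int(i), int(j)) == pytest.approx(4.0)

    def test_corridor_beats_background(self):
        import networkx as nx

        vals = np.full((3, 3), 1.01)
        vals[0, :] = 2.0  # L-shaped high-conductance corridor
        vals[:, 2] = 2.0
        g = graph_from(vals, connectivity=4)
        i, j = int(g.node_of_cell[0, 0]), int(g.node_of_cell[2, 2])
        cost, path = res.lcp_distance(g, i, j, return_path=True)
        # exhaustive simple-path oracle
        G = nx.Graph()
        for (a, b), c in zip(g.edges, g.conductances):
            G.add_edge(int(a), int(b), weight=1.0 / c)
        best = min(sum(G[u][v]["weight"] for u, v in zip(p, p[1:]))
                   for p in nx.all_simple_paths(G, i, j))
        assert cost == pytest.approx(best)
        corridor_cells = {int(g.node_of_cell[0, k]) for k in range(3)} | \
                         {int(g.node_of_cell[k, 2]) for k in range(3)}
        assert set(path) == corridor_cells

    def test_symmetry(self, rng):
        g = graph_from(rng.uniform(1.0, 2.0, (6, 6)))
        for _ in range(10):
            i, j = rng.integers(0, g.n_nodes, 2)
            if i == j:
                continue
            assert res.lcp_distance(g, int(i), int(j)) == \
                pytest.approx(res.lcp_distance(g, int(j), int(i)))


class TestCommuteDistance:
    def _line(self, k):
        mask = np.ones((3, k), dtype=bool)
        mask[1, :] = False
        return graph_from(np.where(~mask, 1.0, 0.0), connectivity=4, mask=mask)

    def test_single_edge_is_two(self):
        g = self._line(2)
        assert res.commute_distance(g, 0, 1) == pytest.approx(2.0)

    def test_path_three_nodes(self):
        g = self._line(3)
        i, j = int(g.node_of_cell[1, 0]), int(g.node_of_cell[1, 2])
        assert res.commute_distance(g, i, j) == pytest.approx(8.0)
        assert commute_oracle(g, i, j) == pytest.approx(8.0)

    def test_matches_markov_oracle_random(self, rng):
        for _ in range(10):
            g = graph_from(rng.uniform(0.5, 3.0, (4, 4)))
            i, j = rng.choice(g.n_nodes, 2, replace=False)
            assert res.commute_distance(g, int(i), int(j)) == \
                pytest.approx(commute_oracle(g, int(i), int(j)), abs=1e-8)

    def test_conductance_scaling_leaves_cd_unchanged(self, rng):
        vals = rng.uniform(0.5, 3.0, (5, 5))
        g1 = graph_from(vals)
        g2 = graph_from(2.0 * vals)
        assert res.commute_distance(g2, 0, 20) == \
            pytest.approx(res.commute_distance(g1, 0, 20), rel=1e-10)

    def test_rayleigh_effective_resistance_bound(self, rng):
        # parallel paths only lower resistance: R_eff <= LCP resistance
        for _ in range(20):
            g = graph_from(rng.uniform(0.5, 3.0, (5, 5)))
            i, j = rng.choice(g.n_nodes, 2, replace=False)
            reff = res.commute_distance(g, int(i), int(j)) / g.volume
            assert reff <= res.lcp_distance(g, int(i), int(j)) + 1e-12

    def test_sparse_solver_matches_dense(self, rng, monkeypatch):
        vals = rng.uniform(0.5, 3.0, (6, 6))
        g = graph_from(vals)
        nodes = np.array([0, 7, 35])
        dense = res.commute_matrix(g, nodes)
        monkeypatch.setattr(res, "DENSE_NODE_LIMIT", 1)
        sparse = res.commute_matrix(g, nodes)
        np.testing.assert_allclose(sparse, dense, atol=1e-6)


class TestEuclideanAndTable:
    def test_three_four_five(self):
        s = SiteSet(["a", "b"], [0.0, 3.0], [0.0, 4.0])
        m = res.euclidean_matrix(s).to_numpy()
        assert m[0, 1] == pytest.approx(5.0)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0)

    def test_translation_invariance(self, rng):
        xy = rng.uniform(0, 100, (5, 2))
        s1 = SiteSet([f"s{i}" for i in range(5)], xy[:, 0], xy[:, 1])
        s2 = SiteSet([f"s{i}" for i in range(5)], xy[:, 0] + 1e4, xy[:, 1] - 5e3)
        np.testing.assert_allclose(res.euclidean_matrix(s1).to_numpy(),
                                   res.euclidean_matrix(s2).to_numpy())

    def test_resistance_table_columns(self, rng):
        hsm = Raster(rng.random((20, 20)), cell_size=100.0, origin=(0.0, 2000.0))
        s = SiteSet(["a", "b", "c"], [250.0, 1750.0, 950.0],
                    [250.0, 1750.0, 1050.0])
        t = res.resistance_table(hsm, s)
        assert list(t.columns) == ["site_i", "site_j", "lcp", "cd", "euclid"]
        assert len(t) == 3
        assert (t[["lcp", "cd", "euclid"]].to_numpy() > 0).all()
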