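"""Resistance-based connectivity: conductance surface, LCP and commute distance.

The habitat-quality surface H (values in [0, 1]) is transformed to a
conductance surface ``C = 1 + H**3``, which compresses contrast among good
habitat and stretches it among poor habitat.  Valid cells become graph
nodes; 4- or 8-neighbors are joined by edges whose conductance is the mean
of the two cell conductances divided by the center-to-center distance in
cell units (1 for rook moves, sqrt(2) for diagonal moves — the standard
geo-correction).

* Least-cost-path (LCP) distance is the minimal cumulative resistance
  ``sum(1/g_e)`` along any path — the single most conductive corridor.
* Commute distance (CD) is the expected random-walk round trip,
  ``Vol(G) * R_eff(i, j)`` with ``Vol(G)`` twice the total edge
  conductance and the effective resistance taken from the graph Laplacian
  (dense pseudoinverse for small graphs, one sparse factorization with
  per-pair solves for large ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .raster import Raster
from .sites import SiteSet, pair_index, pairwise_frame

__all__ = [
    "conductance",
    "TransitionGraph",
    "build_graph",
    "lcp_distance",
    "commute_distance",
    "euclidean_matrix",
    "resistance_table",
]

DENSE_NODE_LIMIT = 3000


def conductance(hsm: Raster) -> Raster:
    """Cubic conductance transform ``C = 1 + H**3`` of a [0, 1] suitability raster."""
    vals = np.asarray(hsm.values, dtype=float)
    valid = ~hsm.mask
    if valid.any():
        lo, hi = vals[valid].min(), vals[valid].max()
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(
                f"habitat quality must lie in [0, 1]; found range [{lo}, {hi}]")
    out = 1.0 + np.clip(vals, 0.0, 1.0) ** 3
    out[hsm.mask] = np.nan
    return Raster(out, hsm.cell_size, hsm.origin, hsm.mask.copy())


@dataclass
class TransitionGraph:
    """Sparse conductance-weighted graph over the valid cells of a raster."""

    n_nodes: int
    edges: np.ndarray        # (n_edges, 2) node indices, i < j
    conductances: np.ndarray
    node_of_cell: np.ndarray  # raster-shaped, -1 for masked cells
    raster: Raster

    def adjacency(self) -> sparse.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        g = self.conductances
        return sparse.coo_matrix(
            (np.concatenate([g, g]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes)).tocsr()

    def resistance_graph(self) -> sparse.csr_matrix:
        adj = self.adjacency()
        adj.data = 1.0 / adj.data
        return adj

    def laplacian(self) -> sparse.csr_matrix:
        adj = self.adjacency()
        deg = np.asarray(adj.sum(axis=1)).ravel()
        return (sparse.diags(deg) - adj).tocsr()

    @property
    def volume(self) -> float:
        return 2.0 * float(self.conductances.sum())

    def node_at(self, raster_xy: tuple[float, float]) -> int:
        row, col = self.raster.cell_of(*raster_xy)
        if not (0 <= row < self.raster.nrows and 0 <= col < self.raster.ncols):
            raise ValueError(f"point {raster_xy} outside the raster extent")
        node = int(self.node_of_cell[row, col])
        if node < 0:
            raise ValueError(f"point {raster_xy} falls on a masked cell")
        return node


def build_graph(cond: Raster, connectivity: int = 8) -> TransitionGraph:
    """Build the transition graph of a conductance raster.

    Edge conductance is the mean of the two endpoint conductances divided
    by the move length in cell units.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    valid = ~cond.mask
    if valid.sum() < 2:
        raise ValueError("need at least two valid cells")
    n, m = cond.shape
    node_of_cell = np.full((n, m), -1, dtype=np.int64)
    node_of_cell[valid] = np.arange(valid.sum())
    vals = np.asarray(cond.values, dtype=float)

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]
    src, dst, g = [], [], []
    for dr, dc, dist in offsets:
        r0, r1 = max(-dr, 0), n - max(dr, 0)
        c0, c1 = max(-dc, 0), m - max(dc, 0)
        a = node_of_cell[r0:r1, c0:c1]
        b = node_of_cell[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        ok = (a >= 0) & (b >= 0)
        va = vals[r0:r1, c0:c1][ok]
        vb = vals[r0 + dr:r1 + dr, c0 + dc:c1 + dc][ok]
        src.append(a[ok])
        dst.append(b[ok])
        g.append((va + vb) / 2.0 / dist)
    edges = np.column_stack([np.concatenate(src), np.concatenate(dst)])
    lo = edges.min(axis=1)
    hi = edges.max(axis=1)
    edges = np.column_stack([lo, hi])
    cond_arr = np.concatenate(g)
    if (cond_arr <= 0).any():
        raise ValueError("all edge conductances must be positive")
    return TransitionGraph(int(valid.sum()), edges, cond_arr, node_of_cell, cond)


def _check_connected(graph: TransitionGraph, nodes: np.ndarray) -> None:
    n_comp, labels = csgraph.connected_components(graph.adjacency(), directed=False)
    if n_comp > 1 and len(set(labels[nodes])) > 1:
        stranded = [int(v) for v in nodes[labels[nodes] != labels[nodes[0]]]]
        raise ValueError(f"sites on disconnected components: nodes {stranded}")


def lcp_distance(graph: TransitionGraph, node_i: int, node_j: int,
                 return_path: bool = False):
    """Least-cost (minimal cumulative resistance) distance between two nodes."""
    res = graph.resistance_graph()
    dist, pred = csgraph.dijkstra(res, directed=False, indices=node_i,
                                  return_predecessors=True)
    cost = float(dist[node_j])
    if np.isinf(cost):
        raise ValueError(f"node {node_j} unreachable from node {node_i}")
    if not return_path:
        return cost
    path = [node_j]
    while path[-1] != node_i:
        path.append(int(pred[path[-1]]))
    return cost, path[::-1]


def commute_distance(graph: TransitionGraph, node_i: int, node_j: int) -> float:
    """Expected random-walk commute time ``Vol(G) * R_eff(i, j)``."""
    return float(commute_matrix(graph, np.array([node_i, node_j]))[0, 1])


def commute_matrix(graph: TransitionGraph, nodes: np.ndarray) -> np.ndarray:
    """Pairwise commute distances among ``nodes`` (one Laplacian solve)."""
    nodes = np.asarray(nodes)
    _check_connected(graph, nodes)
    L = graph.laplacian()
    n = graph.n_nodes
    if n <= DENSE_NODE_LIMIT:
        Lp = np.linalg.pinv(L.toarray(), hermitian=True)
        sub = Lp[np.ix_(nodes, nodes)]
        d = np.diag(sub)
        reff = d[:, None] + d[None, :] - 2 * sub
    else:
        # ground the last node and solve k systems on the reduced Laplacian
        ground = n - 1
        keep = np.arange(n - 1)
        Lr = L[keep][:, keep].tocsc()
        lu = splu(Lr)
        k = len(nodes)
        pots = np.zeros((k, n))
        for a, na in enumerate(nodes):
            rhs = np.zeros(n - 1)
            if na != ground:
                rhs[na] = 1.0
            # current injected at na, extracted at ground
            pots[a, :n - 1] = lu.solve(rhs)
        reff = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                # R_eff = v(na) - v(nb) for unit current na -> ground minus
                # superposition with nb -> ground
                reff[a, b] = (pots[a, nodes[a]] - pots[a, nodes[b]]
                              - pots[b, nodes[a]] + pots[b, nodes[b]])
    return graph.volume * reff


def euclidean_matrix(sites: SiteSet) -> pd.DataFrame:
    """Square matrix of straight-line distances (meters) between sites."""
    c = sites.coords()
    d = np.hypot(c[:, 0][:, None] - c[:, 0][None, :],
                 c[:, 1][:, None] - c[:, 1][None, :])
    return pd.DataFrame(d, index=sites.site_ids, columns=sites.site_ids)


def resistance_table(hsm: Raster, sites: SiteSet,
                     connectivity: int = 8) -> pd.DataFrame:
    """Pairwise table with ``lcp``, ``cd`` and ``euclid`` predictor columns."""
    cond = conductance(hsm)
    graph = build_graph(cond, connectivity=connectivity)
    nodes = np.array([graph.node_at((x, y)) for x, y in zip(sites.x, sites.y)])
    _check_connected(graph, nodes)

    res = graph.resistance_graph()
    dist = csgraph.dijkstra(res, directed=False, indices=nodes)
    cd = commute_matrix(graph, nodes)
    eu = euclidean_matrix(sites).to_numpy()

    table = pairwise_frame(sites)
    pairs = pair_index(sites)
    idx = {s: k for k, s in enumerate(sites.site_ids)}
    table["lcp"] = [dist[idx[a], nodes[idx[b]]] for a, b in pairs]
    table["cd"] = [cd[idx[a], idx[b]] for a, b in pairs]
    table["euclid"] = [eu[idx[a], idx[b]] for a, b in pairs]
    return table
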