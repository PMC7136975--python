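"""Self-validation harness: oracle checks and parameter-recovery studies.

Each function runs one end-to-end check of the package against an
independent oracle — a closed form, exhaustive path enumeration, a
Markov-chain linear-system solve, an algebraic identity, or a Monte-Carlo
truth — and returns the measured quantity.  The checks are deliberately
desk-scale so the whole harness runs in minutes on one CPU; the pytest
acceptance suite and ``scripts/acceptance.py`` both drive these functions.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import pipeline as pl
from . import resistance as res
from .gsm import fourier_texture_metrics
from .mlpe import PairStructure, fit_mlpe, moran_permutation_test
from .pmm import label_patches, pmm_vector
from .raster import Raster
from .sites import SiteSet
from .synthetic import (MLPESimSpec, SurfaceSpec, generate_surface,
                        simulate_mlpe_response)

__all__ = [
    "commute_oracle_error",
    "lcp_oracle_error",
    "mesh_split_identity_error",
    "sfd_recovery",
    "mlpe_recovery",
    "selection_recovery_rate",
    "moran_type1_rate",
]


def _random_connected_graph(rng):
    """Small random conductance raster whose graph is connected."""
    while True:
        n = int(rng.integers(3, 6))  # 9..25 nodes
        vals = rng.uniform(0.3, 3.0, (n, n))
        mask = rng.random((n, n)) < 0.15
        if mask.all():
            continue
        try:
            graph = res.build_graph(Raster(vals, cell_size=1.0, mask=mask),
                                    connectivity=int(rng.choice([4, 8])))
        except ValueError:
            continue
        from scipy.sparse import csgraph

        n_comp, _ = csgraph.connected_components(graph.adjacency(),
                                                 directed=False)
        if n_comp == 1:
            return graph


def _commute_markov_oracle(graph, i, j):
    """Expected commute time by first-step analysis (hitting-time solve)."""
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


def commute_oracle_error(seed: int = 0, n_graphs: int = 100) -> float:
    """Max |CD - Markov-chain commute-time oracle| over random small graphs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        g = _random_connected_graph(rng)
        i, j = rng.choice(g.n_nodes, 2, replace=False)
        cd = res.commute_distance(g, int(i), int(j))
        oracle = _commute_markov_oracle(g, int(i), int(j))
        worst = max(worst, abs(cd - oracle))
    return worst


def lcp_oracle_error(seed: int = 0, n_rasters: int = 20) -> float:
    """Max |LCP - exhaustive simple-path minimum| on 3x3 and 4x4 rasters."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    worst = 0.0
    for k in range(n_rasters):
        n = 3 if k % 2 == 0 else 4
        vals = rng.uniform(0.3, 3.0, (n, n))
        g = res.build_graph(Raster(vals, cell_size=1.0),
                            connectivity=int(rng.choice([4, 8])))
        i, j = rng.choice(g.n_nodes, 2, replace=False)
        cost = res.lcp_distance(g, int(i), int(j))
        G = nx.Graph()
        for (a, b), c in zip(g.edges, g.conductances):
            G.add_edge(int(a), int(b), weight=1.0 / c)
        brute = min(sum(G[u][v]["weight"] for u, v in zip(p, p[1:]))
                    for p in nx.all_simple_paths(G, int(i), int(j)))
        worst = max(worst, abs(cost - brute))
    return worst


def mesh_split_identity_error(seed: int = 0, n_rasters: int = 200) -> float:
    """Max |mesh * split - total area| over random categorical rasters (ha)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_rasters):
        n = int(rng.integers(8, 24))
        m_classes = int(rng.integers(2, 5))
        vals = rng.integers(1, m_classes + 1, size=(n, n))
        mask = rng.random((n, n)) < 0.1
        if mask.all():
            continue
        patches = label_patches(Raster(vals, cell_size=float(rng.uniform(5, 50)),
                                       mask=mask),
                                connectivity=int(rng.choice([4, 8])))
        v = pmm_vector(patches, include_iji=False)
        worst = max(worst, abs(v["mesh"] * v["split"] - patches.total_area_ha))
    return worst


def sfd_recovery(seed: int = 0, hursts=(0.2, 0.5, 0.8),
                 n_seeds: int = 10, size: int = 256) -> dict[float, float]:
    """Mean |Sfd - (3 - H)| per roughness exponent on synthetic fBm surfaces."""
    out = {}
    for h in hursts:
        errs = []
        for k in range(n_seeds):
            surf = generate_surface(SurfaceSpec(size, size, h, 30.0,
                                                seed=seed * 1000 + k))
            errs.append(abs(fourier_texture_metrics(surf)["Sfd"] - (3.0 - h)))
        out[h] = float(np.mean(errs))
    return out


def mlpe_recovery(seed: int = 0, n_reps: int = 200,
                  beta=(0.0, 1.5, -0.8), sigma_u: float = 0.5,
                  sigma_e: float = 0.5) -> dict[str, float]:
    """Fixed-effect recovery and Wald-interval coverage at 17 sites / 136 pairs.

    Returns the worst absolute bias of the mean estimate across
    coefficients and the joint 95 % interval coverage (percent, pooled
    over slope coefficients).
    """
    rng = np.random.default_rng(seed)
    sites = SiteSet([f"S{i:02d}" for i in range(17)],
                    rng.uniform(0, 20_000, 17), rng.uniform(0, 20_000, 17))
    struct = PairStructure.from_sites(sites)
    beta = np.asarray(beta)
    X = rng.normal(size=(sites.n_pairs, len(beta) - 1))
    estimates, covered, n_ci = [], 0, 0
    for rep in range(n_reps):
        y = simulate_mlpe_response(
            X, sites, MLPESimSpec(beta, sigma_u, sigma_e,
                                  seed=int(rng.integers(2 ** 31))))
        fit = fit_mlpe(y, X, sites, struct=struct)
        estimates.append(fit.beta)
        for k in range(1, len(beta)):
            lo = fit.beta[k] - 1.96 * fit.beta_se[k]
            hi = fit.beta[k] + 1.96 * fit.beta_se[k]
            covered += lo <= beta[k] <= hi
            n_ci += 1
    bias = np.abs(np.mean(estimates, axis=0) - beta)
    return {"max_abs_bias": float(bias.max()),
            "coverage_pct": 100.0 * covered / n_ci}


def selection_recovery_rate(seed: int = 0, n_scenes: int = 5,
                            n_responses: int = 10) -> float:
    """Percent of planted-response runs in which the true approach ranks first.

    The response is planted on two gradient-surface metric columns
    (dominant texture direction and texture direction index) with site
    effects, then all six approaches are dredged and ranked by AIC.
    """
    wins = total = 0
    for s in range(n_scenes):
        cfg = pl.ComparisonConfig(response="planted", seed=seed * 100 + s)
        scene = pl.build_scene(cfg)
        for r in range(n_responses):
            cfg_r = dataclasses.replace(cfg, seed=(seed * 100 + s) * 1000 + r)
            y = pl._response_from_scene(scene, cfg_r)
            report = pl.compare_from_tables(scene, y, cfg_r)
            wins += report.best.iloc[0]["approach"] == cfg.planted_approach
            total += 1
    return 100.0 * wins / total


def moran_type1_rate(seed: int = 0, n_reps: int = 200,
                     alpha: float = 0.05) -> float:
    """Rejection rate (percent) of the Moran permutation test on i.i.d. noise.

    Pair-level residuals are drawn i.i.d. and averaged per site, mirroring
    how the residual-autocorrelation check condenses a fitted model's
    residuals.
    """
    rng = np.random.default_rng(seed)
    sites = SiteSet([f"S{i:02d}" for i in range(17)],
                    rng.uniform(0, 20_000, 17), rng.uniform(0, 20_000, 17))
    from .mlpe import incidence_matrix
    from .sites import pair_index

    Z = incidence_matrix(pair_index(sites), sites)
    counts = Z.sum(axis=0)
    rejections = 0
    for rep in range(n_reps):
        resid = rng.normal(size=sites.n_pairs)
        site_resid = Z.T @ resid / counts
        _, p = moran_permutation_test(site_resid, sites,
                                      seed=int(rng.integers(2 ** 31)))
        rejections += p <= alpha
    return 100.0 * rejections / n_reps
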