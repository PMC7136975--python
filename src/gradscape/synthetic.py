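"""Synthetic study inputs: surfaces, land cover, sites, genotypes, responses.

Everything the real study inherited from earlier fieldwork — a continuous
habitat-suitability surface, a categorical land-cover mosaic, sampling
sites, microsatellite genotypes and a pairwise response with known mixed-
model structure — can be generated here from explicit specs, so that the
whole comparison pipeline is testable end to end without external data.
All generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Raster, moving_window_mean  # noqa: F401  (re-export)
from .sites import SiteSet, pair_index

__all__ = [
    "SurfaceSpec",
    "MLPESimSpec",
    "generate_surface",
    "classify_landcover",
    "moving_window_mean",
    "place_sites",
    "simulate_mlpe_response",
    "simulate_microsatellites",
    "FOUNDER_ALLELES",
]

#: Founder allele pool per locus: a realistic dinucleotide repeat ladder.
FOUNDER_ALLELES = np.array([10, 12, 14, 16, 18])


@dataclass
class SurfaceSpec:
    """Spec for a fractional-Brownian habitat-suitability surface.

    ``hurst`` is the roughness exponent H of the field: its power spectrum
    decays as ``f**-(2H + 2)``, so larger H means a smoother surface.
    """

    nrows: int = 256
    ncols: int = 256
    hurst: float = 0.5
    cell_size: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hurst < 1:
            raise ValueError("hurst must lie in (0, 1)")
        if min(self.nrows, self.ncols) < 16:
            raise ValueError("grid must be at least 16x16 for spectral synthesis")


@dataclass
class MLPESimSpec:
    """Planted parameters for a pairwise response with MLPE structure.

    The response for pair (i, j) is ``y = X @ beta + u_i + u_j + eps`` with
    site effects ``u ~ N(0, sigma_u**2)`` and pair residuals
    ``eps ~ N(0, sigma_e**2)``.  ``beta[0]`` is the intercept.
    """

    beta: np.ndarray
    sigma_u: float = 0.5
    sigma_e: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be non-negative")
        if not self.sigma_e > 0:
            raise ValueError("sigma_e must be positive")


def generate_surface(spec: SurfaceSpec) -> Raster:
    """Fractional-Brownian surface by Fourier spectral synthesis.

    Spectral amplitudes are set exactly to ``f**-(beta_psd / 2)`` with
    ``beta_psd = 2 * hurst + 2`` and Hermitian-symmetric random phases, so a
    periodogram regression on the output recovers the planted spectral
    slope.  The result is min-max rescaled to [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.nrows, spec.ncols
    beta_psd = 2.0 * spec.hurst + 2.0
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.rfftfreq(m)[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        amp = np.where(f > 0, f ** (-beta_psd / 2.0), 0.0)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=amp.shape)
    spec_grid = amp * np.exp(1j * phase)
    # columns 0 and (for even m) m//2 must be Hermitian in the row direction
    sym_cols = [0] + ([m // 2] if m % 2 == 0 else [])
    for j in sym_cols:
        for i in range(1, (n + 1) // 2):
            spec_grid[n - i, j] = np.conj(spec_grid[i, j])
        spec_grid[0, j] = spec_grid[0, j].real
        if n % 2 == 0:
            spec_grid[n // 2, j] = spec_grid[n // 2, j].real
    field = np.fft.irfft2(spec_grid, s=(n, m))
    lo, hi = field.min(), field.max()
    field = (field - lo) / (hi - lo)
    return Raster(field, spec.cell_size, (0.0, float(n) * spec.cell_size))


def classify_landcover(surface: Raster, breaks: tuple[float, float]) -> Raster:
    """Threshold a [0, 1] suitability surface into a 3-class cover mosaic.

    Class 1 = forest habitat (``>= t2``), class 2 = complementary habitat
    (shrub/grass analog, ``[t1, t2)``), class 3 = non-habitat (``< t1``).
    """
    t1, t2 = breaks
    if not 0 < t1 < t2 < 1:
        raise ValueError("breaks must satisfy 0 < t1 < t2 < 1")
    vals = np.asarray(surface.values, dtype=float)
    classes = np.full(vals.shape, 3, dtype=np.int32)
    classes[vals >= t1] = 2
    classes[vals >= t2] = 1
    return Raster(classes, surface.cell_size, surface.origin, surface.mask.copy())


def place_sites(raster: Raster, n: int, min_sep: float, seed: int = 0,
                max_attempts: int | None = None, margin: float = 0.0) -> SiteSet:
    """Place ``n`` sites on valid cells with all pairwise separations >= ``min_sep``.

    Rejection sampling on valid cell centers; raises if the attempt budget
    is exhausted (infeasible packing).  ``margin`` keeps sites at least
    that far (meters) from the raster border, so pairwise neighborhoods
    around the sites are not badly truncated at the edge.
    """
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    ok = ~raster.mask
    if margin > 0:
        k = int(np.ceil(margin / raster.cell_size))
        if 2 * k >= min(raster.shape):
            raise ValueError("margin leaves no interior cells")
        interior = np.zeros_like(ok)
        interior[k:-k, k:-k] = True
        ok = ok & interior
    rows, cols = np.nonzero(ok)
    if len(rows) == 0:
        raise ValueError("raster has no valid cells")
    budget = max_attempts if max_attempts is not None else 2000 * n
    xs: list[float] = []
    ys: list[float] = []
    attempts = 0
    while len(xs) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} sites at min_sep={min_sep} within "
                f"{budget} attempts; relax min_sep or enlarge the raster")
        attempts += 1
        k = rng.integers(len(rows))
        cx, cy = raster.cell_center(int(rows[k]), int(cols[k]))
        if all((cx - px) ** 2 + (cy - py) ** 2 >= min_sep ** 2
               for px, py in zip(xs, ys)):
            xs.append(cx)
            ys.append(cy)
    ids = [f"S{i + 1:02d}" for i in range(n)]
    return SiteSet(ids, np.array(xs), np.array(ys))


def simulate_mlpe_response(X: np.ndarray | pd.DataFrame, sites: SiteSet,
                           spec: MLPESimSpec) -> np.ndarray:
    """Draw a pairwise response with planted fixed effects and site effects.

    ``X`` holds the predictor columns (no intercept column); ``spec.beta``
    is ``(intercept, slopes...)``.  Row order must match
    :func:`gradscape.sites.pair_index`.
    """
    Xa = np.asarray(X, dtype=float)
    if Xa.ndim == 1:
        Xa = Xa[:, None]
    pairs = pair_index(sites)
    if Xa.shape[0] != len(pairs):
        raise ValueError(
            f"X has {Xa.shape[0]} rows but the pair universe has {len(pairs)}")
    if Xa.shape[1] != len(spec.beta) - 1:
        raise ValueError("beta length must be number of predictors + 1 (intercept)")
    rng = np.random.default_rng(spec.seed)
    u = rng.normal(0.0, spec.sigma_u, size=sites.n)
    eps = rng.normal(0.0, spec.sigma_e, size=len(pairs))
    idx = {s: k for k, s in enumerate(sites.site_ids)}
    ui = np.array([u[idx[a]] + u[idx[b]] for a, b in pairs])
    return spec.beta[0] + Xa @ spec.beta[1:] + ui + eps


def simulate_microsatellites(sites: SiteSet, n_ind_per_site: int = 27,
                             n_loci: int = 10, migration_scale: float = 50_000.0,
                             mutation_rate: float = 1e-3,
                             n_generations: int = 200,
                             base_migration: float = 0.05,
                             seed: int = 0) -> pd.DataFrame:
    """Forward-in-time island-model microsatellite simulation.

    One deme per site.  Each generation, every offspring gamete is drawn
    from deme ``j`` with probability ``base_migration * exp(-d_ij /
    migration_scale)`` (clipped so total immigration stays below 0.95) and
    otherwise from the home deme; alleles mutate stepwise by +/-1 repeat
    with probability ``mutation_rate``.  Demes start from a common founder
    pool of 5 alleles per locus (sizes 10..18).

    Returns a long-format genotype table with columns ``individual_id,
    population_id, locus, allele1, allele2``.
    """
    if min(n_ind_per_site, n_loci, n_generations) < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    P, I, L = sites.n, n_ind_per_site, n_loci

    coords = sites.coords()
    d = np.hypot(coords[:, 0][:, None] - coords[:, 0][None, :],
                 coords[:, 1][:, None] - coords[:, 1][None, :])
    with np.errstate(over="ignore"):
        M = base_migration * np.exp(-d / migration_scale)
    np.fill_diagonal(M, 0.0)
    row_tot = M.sum(axis=1)
    over = row_tot > 0.95
    if over.any():  # keep a minimum 5% philopatry
        M[over] *= (0.95 / row_tot[over])[:, None]
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))

    alleles = rng.choice(FOUNDER_ALLELES, size=(P, I, L, 2)).astype(np.int64)
    pop_ix = np.arange(P)
    for _ in range(n_generations):
        # source deme of each gamete, then parent individual and allele copy
        src = np.empty((P, I, 2), dtype=np.int64)
        for p in range(P):
            src[p] = rng.choice(pop_ix, size=(I, 2), p=M[p])
        parent = rng.integers(I, size=(P, I, 2))
        which = rng.integers(2, size=(P, I, 2, L))
        new = alleles[src[..., None], parent[..., None],
                      np.arange(L)[None, None, None, :], which]
        new = np.transpose(new, (0, 1, 3, 2))  # -> (P, I, L, 2)
        mut = rng.random(size=new.shape) < mutation_rate
        step = rng.choice([-1, 1], size=new.shape)
        new = new + mut * step
        alleles = np.maximum(new, 1)  # repeat counts stay positive

    records = []
    for p, site in enumerate(sites.site_ids):
        for i in range(I):
            ind = f"{site}_{i + 1:03d}"
            for l in range(L):
                records.append((ind, site, f"L{l + 1:02d}",
                                int(alleles[p, i, l, 0]), int(alleles[p, i, l, 1])))
    return pd.DataFrame(records, columns=["individual_id", "population_id",
                                          "locus", "allele1", "allele2"])
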