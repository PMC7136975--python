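"""Pairwise genetic distances from microsatellite genotypes.

Two population-pairwise dissimilarities are implemented:

* ``R_ST`` — allele-size variance components under a stepwise-mutation
  view of microsatellite evolution.  For each population pair and locus, a
  one-way ANOVA on allele sizes (alleles as observations, population as
  factor) yields an among-population component ``sigma2_a`` (expected mean
  squares with the unequal-sample-size correction ``n0``) and a
  within-population component ``sigma2_w``; loci are combined by summing
  components before forming ``R_ST = sum(sigma2_a) / sum(sigma2_a +
  sigma2_w)``.  Negative per-locus among components are floored at zero by
  default so distances stay in [0, 1].

* ``D_PS`` — one minus the proportion of shared alleles: per locus
  ``PS = sum_a min(p_a, q_a)`` over the two populations' allele
  frequencies, averaged over co-typed loci; motivated by the
  infinite-allele view.

Genotype tables are long-format DataFrames with columns ``individual_id,
population_id, locus, allele1, allele2``; missing alleles are NaN/empty
and dropped per locus (available-case).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "rst_matrix",
    "dps_matrix",
    "pairwise_rst",
    "pairwise_dps",
]

GENOTYPE_COLUMNS = ["individual_id", "population_id", "locus", "allele1", "allele2"]


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing column(s): {missing}")
    return df


def write_genotypes(genotypes: pd.DataFrame, path: str | Path) -> None:
    genotypes.to_csv(path, index=False)


def _allele_arrays(genotypes: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """Per population, per locus: flat array of (non-missing) allele sizes."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for (pop, locus), grp in genotypes.groupby(["population_id", "locus"], sort=False):
        alleles = pd.concat([grp["allele1"], grp["allele2"]]).to_numpy(dtype=float)
        alleles = alleles[~np.isnan(alleles)]
        out.setdefault(str(pop), {})[str(locus)] = alleles
    return out


def _rst_components(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-locus ANOVA variance components (among, within) for two samples."""
    na, nb = len(a), len(b)
    N = na + nb
    grand = (a.sum() + b.sum()) / N
    ssa = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    msw = ssw / (N - 2)
    msa = ssa / 1.0  # k - 1 = 1 for a pair
    n0 = (N - (na * na + nb * nb) / N) / 1.0
    sigma2_a = (msa - msw) / n0
    return sigma2_a, msw


def pairwise_rst(genotypes: pd.DataFrame, pop_a: str, pop_b: str,
                 floor_negative: bool = True) -> float:
    """R_ST between two populations, combining loci by summed components."""
    arrays = _allele_arrays(genotypes)
    return _rst_from_arrays(arrays, pop_a, pop_b, floor_negative)


def _rst_from_arrays(arrays, pop_a: str, pop_b: str, floor_negative: bool) -> float:
    loci = set(arrays.get(pop_a, {})) & set(arrays.get(pop_b, {}))
    num = den = 0.0
    n_used = 0
    for locus in sorted(loci):
        a, b = arrays[pop_a][locus], arrays[pop_b][locus]
        if len(a) < 2 or len(b) < 2:
            continue
        s_a, s_w = _rst_components(a, b)
        if floor_negative:
            s_a = max(s_a, 0.0)
        num += s_a
        den += s_a + s_w
        n_used += 1
    if n_used == 0:
        warnings.warn(f"no co-typed locus for pair ({pop_a}, {pop_b})")
        return np.nan
    if den == 0.0:  # both populations monomorphic and identical
        return 0.0
    return float(np.clip(num / den, 0.0, 1.0))


def _freqs(alleles: np.ndarray) -> dict[float, float]:
    vals, counts = np.unique(alleles, return_counts=True)
    tot = counts.sum()
    return {float(v): c / tot for v, c in zip(vals, counts)}


def pairwise_dps(genotypes: pd.DataFrame, pop_a: str, pop_b: str) -> float:
    """D_PS = 1 - mean over co-typed loci of the shared-allele proportion."""
    arrays = _allele_arrays(genotypes)
    return _dps_from_arrays(arrays, pop_a, pop_b)


def _dps_from_arrays(arrays, pop_a: str, pop_b: str) -> float:
    loci = set(arrays.get(pop_a, {})) & set(arrays.get(pop_b, {}))
    shared = []
    for locus in sorted(loci):
        a, b = arrays[pop_a][locus], arrays[pop_b][locus]
        if len(a) == 0 or len(b) == 0:
            continue
        p, q = _freqs(a), _freqs(b)
        shared.append(sum(min(p[al], q.get(al, 0.0)) for al in p))
    if not shared:
        warnings.warn(f"no co-typed locus for pair ({pop_a}, {pop_b})")
        return np.nan
    return float(np.clip(1.0 - np.mean(shared), 0.0, 1.0))


def _matrix(genotypes: pd.DataFrame, func, populations=None, **kwargs) -> pd.DataFrame:
    arrays = _allele_arrays(genotypes)
    if populations is None:
        populations = list(dict.fromkeys(genotypes["population_id"].astype(str)))
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    n = len(populations)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = func(arrays, populations[i], populations[j],
                                         **kwargs)
    return pd.DataFrame(mat, index=populations, columns=populations)


def rst_matrix(genotypes: pd.DataFrame, populations: list[str] | None = None,
               floor_negative: bool = True) -> pd.DataFrame:
    """Square symmetric R_ST matrix over populations (site order preserved)."""
    return _matrix(genotypes, _rst_from_arrays, populations,
                   floor_negative=floor_negative)


def dps_matrix(genotypes: pd.DataFrame,
               populations: list[str] | None = None) -> pd.DataFrame:
    """Square symmetric D_PS matrix over populations."""
    return _matrix(genotypes, _dps_from_arrays, populations)
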