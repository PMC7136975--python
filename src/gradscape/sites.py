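"""Sampling sites and the pairwise-record table.

A :class:`SiteSet` is an ordered collection of named sampling locations in
projected meters.  Every downstream stage works on the universe of
unordered site pairs — ``n(n-1)/2`` of them — materialised as a pandas
DataFrame with ``site_i``/``site_j`` key columns ("PairwiseTable").  Pair
order is fixed by site order, not alphabetically, so joins across modules
are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SiteSet",
    "pair_index",
    "pairwise_frame",
    "read_sites",
    "write_sites",
    "read_square_matrix",
    "square_from_pairs",
    "write_pairwise",
    "read_pairwise",
]

SYMMETRY_TOL = 1e-9


@dataclass
class SiteSet:
    """Ordered sampling locations with unique ids and projected coordinates."""

    site_ids: list[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.site_ids = [str(s) for s in self.site_ids]
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.site_ids) != len(self.x) or len(self.x) != len(self.y):
            raise ValueError("site_ids, x and y must have equal length")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site_ids must be unique")

    @property
    def n(self) -> int:
        return len(self.site_ids)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def index_of(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def __len__(self) -> int:
        return self.n


def pair_index(sites: SiteSet) -> list[tuple[str, str]]:
    """All unordered site pairs, lexicographic in site *order* (i < j)."""
    if sites.n < 2:
        raise ValueError("need at least 2 sites to form pairs")
    ids = sites.site_ids
    return [(ids[i], ids[j]) for i in range(sites.n) for j in range(i + 1, sites.n)]


def pairwise_frame(sites: SiteSet) -> pd.DataFrame:
    """Empty pairwise table keyed by (site_i, site_j) in canonical order."""
    pairs = pair_index(sites)
    return pd.DataFrame({"site_i": [p[0] for p in pairs],
                         "site_j": [p[1] for p in pairs]})


def read_sites(path: str | Path) -> SiteSet:
    df = pd.read_csv(path)
    required = {"site_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"site table must have columns {sorted(required)}")
    return SiteSet(list(df["site_id"].astype(str)), df["x"].to_numpy(), df["y"].to_numpy())


def write_sites(sites: SiteSet, path: str | Path) -> None:
    pd.DataFrame({"site_id": sites.site_ids, "x": sites.x, "y": sites.y}).to_csv(
        path, index=False)


def read_square_matrix(path: str | Path, sites: SiteSet | None = None,
                       column: str = "value") -> pd.DataFrame:
    """Read a labeled square symmetric matrix CSV into a pairwise table.

    The CSV must carry identical row and column labels and be symmetric to
    within ``SYMMETRY_TOL``.  The lower triangle is flattened to one record
    per unordered pair; when ``sites`` is given, pair order follows the
    site order and labels must match the site ids.
    """
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    row_labels = [str(r) for r in df.index]
    if labels != row_labels:
        raise ValueError("row and column labels of the square matrix differ")
    mat = df.to_numpy(dtype=float)
    asym = np.abs(mat - mat.T)
    worst = np.unravel_index(np.nanargmax(asym), asym.shape)
    if asym[worst] > SYMMETRY_TOL:
        raise ValueError(
            f"matrix asymmetric: |M[{worst[0]},{worst[1]}] - M[{worst[1]},{worst[0]}]|"
            f" = {asym[worst]:.3g} exceeds tolerance {SYMMETRY_TOL}")
    if sites is not None:
        if set(labels) != set(sites.site_ids):
            raise ValueError("matrix labels do not match site ids")
        order = [labels.index(s) for s in sites.site_ids]
        mat = mat[np.ix_(order, order)]
        labels = list(sites.site_ids)
    n = len(labels)
    recs = [(labels[i], labels[j], mat[j, i]) for i in range(n) for j in range(i + 1, n)]
    return pd.DataFrame(recs, columns=["site_i", "site_j", column])


def square_from_pairs(table: pd.DataFrame, column: str,
                      sites: SiteSet) -> pd.DataFrame:
    """Inverse of :func:`read_square_matrix`: pairwise column -> square matrix."""
    n = sites.n
    mat = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(sites.site_ids)}
    for _, row in table.iterrows():
        i, j = idx[str(row["site_i"])], idx[str(row["site_j"])]
        mat[i, j] = mat[j, i] = row[column]
    return pd.DataFrame(mat, index=sites.site_ids, columns=sites.site_ids)


def write_pairwise(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_pairwise(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "site_i" not in df.columns or "site_j" not in df.columns:
        raise ValueError("pairwise table must have site_i and site_j columns")
    return df
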