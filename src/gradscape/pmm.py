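"""Patch-mosaic landscape metrics on categorical cover rasters.

The land-cover mosaic is reclassified into either three classes (forest
habitat = 1, complementary habitat = 2, non-habitat = 3; "PMM3") or two
classes with non-habitat masked out ("PMM2").  Patches are connected
components per class (8-connectivity by default, the landscapemetrics
convention), and ten landscape-level metrics are computed per clip:

``np`` number of patches, ``pd`` patch density (per 100 ha), ``ed`` edge
density (m/ha), ``area_mn`` mean patch area (ha), ``core_mn`` mean core
area (ha), ``cai_mn`` mean core-area index (%), ``prd`` patch richness
density (per 100 ha), ``iji`` interspersion/juxtaposition index (%,
undefined for fewer than three classes), ``split`` splitting index and
``mesh`` effective mesh size (ha).  ``mesh * split`` equals the total
valid area exactly — an algebraic identity used as a cross-check.

Edges are counted between 4-adjacent valid cells of differing class;
landscape-boundary faces are excluded by default (clipped landscapes),
toggleable via ``include_boundary_edge``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import Raster

__all__ = ["PatchMap", "reclassify", "label_patches", "pmm_vector", "PMM_NAMES"]

PMM_NAMES = ["np", "pd", "ed", "area_mn", "core_mn", "cai_mn", "prd", "iji",
             "split", "mesh"]

_STRUCT = {4: ndimage.generate_binary_structure(2, 1),
           8: ndimage.generate_binary_structure(2, 2)}


class MetricUndefinedError(ValueError):
    pass


@dataclass
class PatchMap:
    """Labeled patches of a categorical raster.

    ``labels`` assigns an integer patch id per cell (0 = masked);
    per-patch class, cell count and core cell count are parallel arrays
    indexed by ``patch id - 1``.
    """

    labels: np.ndarray
    patch_class: np.ndarray
    patch_cells: np.ndarray
    patch_core_cells: np.ndarray
    cell_size: float
    classes: list[int]
    edge_lengths: dict[tuple[int, int], float]  # inter-class edge, meters
    boundary_edge: float  # valid-to-outside/masked edge, meters

    @property
    def n_patches(self) -> int:
        return len(self.patch_class)

    @property
    def patch_areas_ha(self) -> np.ndarray:
        return self.patch_cells * self.cell_size ** 2 / 10_000.0

    @property
    def core_areas_ha(self) -> np.ndarray:
        return self.patch_core_cells * self.cell_size ** 2 / 10_000.0

    @property
    def total_area_ha(self) -> float:
        return float(self.patch_cells.sum()) * self.cell_size ** 2 / 10_000.0


def reclassify(landcover: Raster, class_map: dict[int, int],
               scheme: str = "pmm3") -> Raster:
    """Map source cover classes onto {1, 2, 3}; under PMM2, mask class 3.

    ``class_map`` must cover every source class present among valid cells;
    an unmapped class raises with the offending value named.
    """
    scheme = scheme.lower()
    if scheme not in ("pmm3", "pmm2"):
        raise ValueError("scheme must be 'pmm3' or 'pmm2'")
    vals = np.asarray(landcover.values)
    present = set(int(v) for v in np.unique(vals[~landcover.mask]))
    unmapped = sorted(present - set(class_map))
    if unmapped:
        raise ValueError(f"unmapped source class(es): {unmapped}")
    out = np.zeros(vals.shape, dtype=np.int32)
    for src, dst in class_map.items():
        if dst not in (1, 2, 3):
            raise ValueError("target classes must be 1, 2 or 3")
        out[vals == src] = dst
    mask = landcover.mask.copy()
    if scheme == "pmm2":
        mask |= out == 3
    return Raster(out, landcover.cell_size, landcover.origin, mask)


def label_patches(classraster: Raster, connectivity: int = 8,
                  edge_depth: int = 1) -> PatchMap:
    """Connected-component patches plus core cells and inter-class edges.

    Core cells are valid same-class cells surviving ``edge_depth``
    erosions with the 8-neighborhood (a cell is core when its Chebyshev
    neighborhood is entirely same-class and valid).  Edge lengths count
    4-adjacent faces between valid cells of differing class, times the
    cell size; faces against masked cells or the raster boundary are
    tallied separately.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    valid = ~classraster.mask
    if not valid.any():
        raise ValueError("no valid cells to label")
    vals = np.where(valid, classraster.values, 0).astype(np.int64)
    classes = sorted(int(c) for c in np.unique(vals[valid]))
    labels = np.zeros(vals.shape, dtype=np.int64)
    patch_class: list[int] = []
    patch_cells: list[int] = []
    patch_core: list[int] = []
    next_label = 1
    core_struct = _STRUCT[8]
    for cls in classes:
        m = (vals == cls) & valid
        lab, n = ndimage.label(m, structure=_STRUCT[connectivity])
        core = ndimage.binary_erosion(m, structure=core_struct,
                                      iterations=edge_depth, border_value=0)
        for k in range(1, n + 1):
            sel = lab == k
            labels[sel] = next_label
            patch_class.append(cls)
            patch_cells.append(int(sel.sum()))
            patch_core.append(int((sel & core).sum()))
            next_label += 1

    cs = classraster.cell_size
    edge: dict[tuple[int, int], float] = {}
    boundary = 0.0
    for axis in (0, 1):
        a = vals if axis == 0 else vals.T
        va = valid if axis == 0 else valid.T
        left, right = a[:-1, :], a[1:, :]
        vleft, vright = va[:-1, :], va[1:, :]
        both = vleft & vright
        diff = both & (left != right)
        for i, j in zip(left[diff].ravel(), right[diff].ravel()):
            key = (int(min(i, j)), int(max(i, j)))
            edge[key] = edge.get(key, 0.0) + cs
        # faces between a valid cell and a masked neighbor
        boundary += cs * float(((vleft & ~vright) | (~vleft & vright)).sum())
        # faces on the outer raster boundary
        boundary += cs * float(va[0, :].sum() + va[-1, :].sum())
    return PatchMap(labels, np.array(patch_class), np.array(patch_cells),
                    np.array(patch_core), cs, classes, edge, boundary)


def pmm_vector(patches: PatchMap, include_iji: bool = True,
               include_boundary_edge: bool = False) -> dict[str, float]:
    """The ten landscape-level metrics from a PatchMap.

    ``iji`` requires at least three classes; requesting it on a two-class
    landscape raises :class:`MetricUndefinedError` (it is omitted under
    PMM2 by passing ``include_iji=False``).
    """
    areas = patches.patch_areas_ha
    A = patches.total_area_ha
    n_p = patches.n_patches
    if n_p < 1 or A <= 0:
        raise ValueError("empty patch map")
    E_inter = sum(patches.edge_lengths.values())
    E = E_inter + (patches.boundary_edge if include_boundary_edge else 0.0)
    m = len(patches.classes)
    cores = patches.core_areas_ha
    with np.errstate(invalid="ignore", divide="ignore"):
        cai = np.where(areas > 0, 100.0 * cores / areas, 0.0)
    out = {
        "np": float(n_p),
        "pd": n_p / A * 100.0,
        "ed": E / A,
        "area_mn": float(areas.mean()),
        "core_mn": float(cores.mean()),
        "cai_mn": float(cai.mean()),
        "prd": m / A * 100.0,
        "split": float(A ** 2 / (areas ** 2).sum()),
        "mesh": float((areas ** 2).sum() / A),
    }
    if include_iji:
        if m < 3:
            raise MetricUndefinedError(
                "iji is not defined for landscapes with fewer than three classes")
        if E_inter <= 0:
            out["iji"] = float("nan")
        else:
            ps = np.array([e / E_inter for e in patches.edge_lengths.values()])
            h = -(ps * np.log(ps)).sum()
            out["iji"] = float(h / np.log(0.5 * m * (m - 1)) * 100.0)
    else:
        out["iji"] = float("nan")
    return {k: out[k] for k in PMM_NAMES}
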