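"""Gridded raster container and file I/O.

A :class:`Raster` is a rectangular grid of cell values with square cells,
a top-left outer-corner origin in projected meters, and a boolean nodata
mask.  Row index increases southward, column index eastward, matching the
GeoTIFF/ESRI convention, so the center of cell ``(row, col)`` sits at
``(origin_x + (col + 0.5) * cell_size, origin_y - (row + 0.5) * cell_size)``.

Two single-band formats are supported: ESRI ASCII grid (plain text) and
GeoTIFF, the latter written through :mod:`tifffile` with the standard
``ModelPixelScale`` / ``ModelTiepoint`` / ``GDAL_NODATA`` tags.  Masked
cells are excluded from every statistic computed downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Raster",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "moving_window_mean",
]

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")

# GeoTIFF tag codes used for georeferencing a single-band image.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Raised for malformed raster files or unsupported geometries."""


@dataclass
class Raster:
    """Square-celled single-band raster with a nodata mask.

    Parameters
    ----------
    values
        2-D array of cell values (float or integer).
    cell_size
        Edge length of a cell in meters; must be positive.
    origin
        ``(x, y)`` of the outer corner of the top-left cell.
    mask
        Boolean array, ``True`` where a cell holds no data.  Defaults to
        all-valid.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("raster grid must be 2-D and at least 2x2")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def valid_values(self) -> np.ndarray:
        """1-D array of the unmasked cell values."""
        return np.asarray(self.values[~self.mask])

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        ox, oy = self.origin
        return (ox + (col + 0.5) * self.cell_size, oy - (row + 0.5) * self.cell_size)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing the point ``(x, y)``."""
        ox, oy = self.origin
        col = int(math.floor((x - ox) / self.cell_size))
        row = int(math.floor((oy - y) / self.cell_size))
        return row, col

    def contains(self, x: float, y: float) -> bool:
        row, col = self.cell_of(x, y)
        return 0 <= row < self.nrows and 0 <= col < self.ncols

    def copy(self) -> "Raster":
        return Raster(self.values.copy(), self.cell_size, self.origin, self.mask.copy())


def read_raster(path: str | Path, fmt: str | None = None) -> Raster:
    """Read a single-band raster from an ESRI ASCII grid or GeoTIFF.

    ``fmt`` may be ``"ascii_grid"`` or ``"geotiff"``; when omitted it is
    inferred from the file suffix (``.asc``/``.txt`` vs ``.tif``/``.tiff``).
    """
    path = Path(path)
    if fmt is None:
        fmt = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def write_raster(raster: Raster, path: str | Path, fmt: str | None = None,
                 nodata: float = -9999.0) -> None:
    """Write a raster, choosing format from ``fmt`` or the file suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "geotiff" if path.suffix.lower() in (".tif", ".tiff") else "ascii_grid"
    if fmt == "ascii_grid":
        _write_ascii(raster, path, nodata)
    elif fmt == "geotiff":
        _write_geotiff(raster, path, nodata)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _read_ascii(path: Path) -> Raster:
    header: dict[str, float] = {}
    nodata = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(f"bad ASCII-grid header value in {key!r}") from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
            n_header += 1
        else:
            break
    missing = [k for k in _ASCII_HEADER_KEYS if k not in header]
    if missing:
        raise RasterFormatError(f"ASCII grid missing header field(s): {', '.join(missing)}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    try:
        values = np.loadtxt(lines[n_header:], ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"unparseable ASCII-grid data block: {exc}") from exc
    if values.shape != (nrows, ncols):
        raise RasterFormatError(
            f"ASCII grid data block is {values.shape}, header says {(nrows, ncols)}")
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = np.isclose(values, nodata)
    mask |= np.isnan(values)
    cs = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cs)
    return Raster(values, cs, origin, mask)


def _write_ascii(raster: Raster, path: Path, nodata: float) -> None:
    ox, oy = raster.origin
    vals = np.array(raster.values, dtype=float)
    vals[raster.mask] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {ox!r}\n")
        fh.write(f"yllcorner {oy - raster.nrows * raster.cell_size!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def _read_geotiff(path: Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        cell_size = 1.0
        if _TAG_MODEL_PIXEL_SCALE in tags:
            sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
            if not math.isclose(sx, sy, rel_tol=1e-9):
                raise RasterFormatError(
                    f"non-square pixels ({sx} x {sy}) are not supported")
            cell_size = float(sx)
        origin = (0.0, 0.0)
        if _TAG_MODEL_TIEPOINT in tags:
            tp = tags[_TAG_MODEL_TIEPOINT].value
            origin = (float(tp[3]), float(tp[4]))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if values.ndim != 2:
        raise RasterFormatError("only single-band GeoTIFFs are supported")
    mask = np.zeros(values.shape, dtype=bool)
    if nodata is not None:
        mask = np.isclose(values.astype(float), nodata)
    if np.issubdtype(values.dtype, np.floating):
        mask |= np.isnan(values)
    return Raster(values, cell_size, origin, mask)


def _write_geotiff(raster: Raster, path: Path, nodata: float) -> None:
    import tifffile

    vals = raster.values
    if np.issubdtype(vals.dtype, np.integer):
        out = vals.astype(np.int32)
        out[raster.mask] = int(nodata)
        nodata_str = str(int(nodata))
    else:
        out = vals.astype(np.float64)
        out[raster.mask] = nodata
        nodata_str = str(nodata)
    ox, oy = raster.origin
    cs = raster.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(str(path), out, extratags=extratags)


def moving_window_mean(raster: Raster, window_edge: float) -> Raster:
    """Focal mean over a centered square window of the given edge length.

    The edge length in meters is rounded to the nearest odd cell count.
    Each output cell holds the mean of the valid cells inside its window;
    cells masked on input stay masked.
    """
    if window_edge < raster.cell_size:
        raise ValueError("window edge must be at least one cell")
    k = int(round(window_edge / raster.cell_size))
    if k % 2 == 0:
        k += 1
    if k > min(raster.shape):
        raise ValueError(f"window of {k} cells exceeds raster extent {raster.shape}")
    from scipy import ndimage

    valid = (~raster.mask).astype(float)
    vals = np.where(raster.mask, 0.0, raster.values.astype(float))
    ksum = ndimage.uniform_filter(vals, size=k, mode="constant", cval=0.0) * k * k
    kcnt = ndimage.uniform_filter(valid, size=k, mode="constant", cval=0.0) * k * k
    kcnt = np.round(kcnt)  # uniform_filter is float; counts are integral
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ksum / kcnt
    out[raster.mask] = np.nan
    return Raster(out, raster.cell_size, raster.origin, raster.mask.copy())
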