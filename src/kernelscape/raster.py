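"""Raster container and file I/O.

Every surface in the pipeline (land cover, resistance, deforestation risk,
kernel density, path density, binary habitat) is a :class:`RasterGrid`: a
rectangular cell matrix in a single planar coordinate system with square
cells, a top-left origin and 0-based row-major indexing.  Row 0 is the
northmost row; cell ``(r, c)`` has its centre at
``(x0 + (c + 0.5) * cell_size, y0 - (r + 0.5) * cell_size)``.

Two on-disk formats are supported and round-trip values, cell size, origin
and nodata losslessly:

* single-band GeoTIFF via :mod:`tifffile`, using the standard
  georeferencing tags (ModelPixelScale, ModelTiepoint, GDAL_NODATA);
* the plain-text ESRI ASCII grid (``.asc``).

No reprojection is performed anywhere: grids either align exactly or the
pipeline refuses them with a loud :class:`AlignmentError`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "AlignmentError",
    "check_aligned",
    "read_raster",
    "write_raster",
]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass
class RasterGrid:
    """A georeferenced cell matrix.

    Parameters
    ----------
    values
        ``rows x cols`` array (float or integer).
    cell_size
        Square cell edge length in metres, ``> 0``.
    origin
        ``(x, y)`` map coordinates of the *upper-left corner* of cell (0, 0).
    nodata
        Sentinel marking missing cells.  NaN cells are also treated as
        missing for float grids.
    """

    values: np.ndarray
    cell_size: float = 1000.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def data_mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata, non-NaN) cells."""
        mask = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= ~np.isnan(self.values)
        return mask

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def copy(self, values: np.ndarray | None = None) -> "RasterGrid":
        """Copy, optionally substituting a new value matrix on the same grid."""
        v = self.values.copy() if values is None else np.asarray(values)
        return RasterGrid(v, self.cell_size, self.origin, self.nodata)

    def __eq__(self, other: object) -> bool:  # value equality, used in tests
        if not isinstance(other, RasterGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.array_equal(self.values, other.values, equal_nan=True)
            and self.cell_size == other.cell_size
            and self.origin == other.origin
            and self.nodata == other.nodata
        )


def check_aligned(*grids: RasterGrid, tol: float = 1e-6) -> None:
    """Verify that all grids share shape, cell size and origin.

    Raises
    ------
    AlignmentError
        Naming the first mismatching attribute.
    """
    if len(grids) < 2:
        raise ValueError("check_aligned needs at least two grids")
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise AlignmentError(f"shape mismatch: {ref.shape} vs {g.shape}")
        if abs(g.cell_size - ref.cell_size) > tol:
            raise AlignmentError(
                f"cell_size mismatch: {ref.cell_size} vs {g.cell_size}"
            )
        if (
            abs(g.origin[0] - ref.origin[0]) > tol
            or abs(g.origin[1] - ref.origin[1]) > tol
        ):
            raise AlignmentError(f"origin mismatch: {ref.origin} vs {g.origin}")


# ---------------------------------------------------------------------------
# GeoTIFF


def _write_geotiff(grid: RasterGrid, path: str) -> None:
    sx = sy = float(grid.cell_size)
    x0, y0 = (float(v) for v in grid.origin)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (sx, sy, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0), True),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata)), True),
    ]
    tifffile.imwrite(path, grid.values, extratags=extratags)


def _read_geotiff(path: str) -> RasterGrid:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        try:
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags") from exc
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    cell = float(scale[0])
    # tiepoint maps raster (i, j, k) -> model (x, y, z); we always write (0, 0)
    x0 = float(tiepoint[3]) - float(tiepoint[0]) * cell
    y0 = float(tiepoint[4]) + float(tiepoint[1]) * cell
    return RasterGrid(values, cell, (x0, y0), nodata)


# ---------------------------------------------------------------------------
# ESRI ASCII grid


def _write_esri_ascii(grid: RasterGrid, path: str) -> None:
    rows, cols = grid.shape
    x0, y0 = grid.origin
    yll = y0 - rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {cols}\n")
        fh.write(f"nrows {rows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for r in range(rows):
            fh.write(" ".join(repr(v) for v in grid.values[r].tolist()))
            fh.write("\n")


def _read_esri_ascii(path: str) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "cellsize",
                "nodata_value",
            } and not data_lines:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: malformed ESRI ASCII grid, missing {req}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    values = np.loadtxt(data_lines, ndmin=2)
    if values.shape != (rows, cols):
        raise ValueError(
            f"{path}: header says {(rows, cols)} but data is {values.shape}"
        )
    if np.allclose(values, np.round(values)) and np.abs(values).max(initial=0) < 2**31:
        # integer-valued grid (e.g. land cover codes): keep integer dtype
        as_int = values.astype(np.int64)
        if np.array_equal(as_int.astype(float), values):
            values = as_int
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * cell)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    return RasterGrid(values, cell, origin, nodata)


# ---------------------------------------------------------------------------
# Dispatch


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in {".tif", ".tiff"}:
        return "geotiff"
    if ext in {".asc", ".txt", ".grd"}:
        return "esri_ascii"
    raise ValueError(f"cannot infer raster format from extension {ext!r}")


def write_raster(grid: RasterGrid, path: str, fmt: str | None = None) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "geotiff":
        _write_geotiff(grid, path)
    elif fmt == "esri_ascii":
        _write_esri_ascii(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def read_raster(path: str, fmt: str | None = None) -> RasterGrid:
    fmt = _infer_format(path, fmt)
    if fmt == "geotiff":
        return _read_geotiff(path)
    if fmt == "esri_ascii":
        return _read_esri_ascii(path)
    raise ValueError(f"unknown raster format {fmt!r}")
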