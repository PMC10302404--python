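"""Aligned raster grids and their I/O.

Every spatial layer in an analysis (land cover, flow direction, flow
accumulation, catchments, soils, streams) is a :class:`RasterGrid`: a
rectangular 2-D array with a cell size in metres, an upper-left origin in
projected coordinates, and a nodata sentinel.  All layers of one analysis
must be mutually aligned (same shape, cell size and origin); alignment is
checked, never assumed.

Two on-disk formats are supported, dispatched on file extension:

* ``.asc`` — ESRI ASCII Grid, a plain-text header + rows format.  Used for
  all committed fixtures because it is human-auditable.
* ``.tif`` / ``.tiff`` — single-band TIFF via :mod:`tifffile`; cell size,
  origin, nodata and layer kind travel in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "AlignmentError",
    "assert_aligned",
    "read_raster",
    "write_raster",
]

LAYER_KINDS = (
    "landcover",
    "flowdir",
    "accumulation",
    "catchment",
    "ksat",
    "drainage",
    "stream",
    "label",
    "dem",
    "generic",
)


class AlignmentError(ValueError):
    """Raised when grids that must share a frame do not."""


@dataclass
class RasterGrid:
    """A single-band raster layer on a regular grid.

    Parameters
    ----------
    values : ndarray
        2-D array of cell values (numeric or category codes).
    cell_size : float
        Edge length of one square pixel in metres (default 30, the
        resolution of the national land-cover and flow grids this
        pipeline was designed around).
    origin : (float, float)
        Projected ``(x, y)`` of the upper-left grid corner.
    nodata : float
        Sentinel marking missing cells.
    layer_kind : str
        Tag describing what the layer holds (see ``LAYER_KINDS``).
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    layer_kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size < 1:
            raise ValueError("grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of nodata cells (NaN-aware)."""
        vals = self.values
        if np.issubdtype(vals.dtype, np.floating):
            return np.isnan(vals) | (vals == self.nodata)
        return vals == self.nodata

    def is_nodata(self, row: int, col: int) -> bool:
        v = self.values[row, col]
        if isinstance(v, (float, np.floating)) and np.isnan(v):
            return True
        return v == self.nodata

    # -- alignment ------------------------------------------------------
    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def like(self, values: np.ndarray, *, layer_kind: str | None = None,
             nodata: float | None = None) -> "RasterGrid":
        """A new grid sharing this grid's frame with different values."""
        return replace(
            self,
            values=np.asarray(values),
            layer_kind=layer_kind if layer_kind is not None else self.layer_kind,
            nodata=nodata if nodata is not None else self.nodata,
        )


def assert_aligned(*grids: RasterGrid) -> None:
    """Raise :class:`AlignmentError` unless all grids share one frame."""
    if len(grids) < 2:
        return
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise AlignmentError(
                f"layer '{g.layer_kind}' (shape {g.shape}, cell {g.cell_size}, "
                f"origin {g.origin}) does not align with layer "
                f"'{ref.layer_kind}' (shape {ref.shape}, cell {ref.cell_size}, "
                f"origin {ref.origin})"
            )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _write_ascii(grid: RasterGrid, path: Path) -> None:
    n_rows, n_cols = grid.shape
    x_ul, y_ul = grid.origin
    yll = y_ul - n_rows * grid.cell_size
    vals = grid.values
    if np.issubdtype(vals.dtype, np.floating):
        body = np.where(np.isnan(vals), grid.nodata, vals)
        fmt = "%.10g"
    else:
        body = vals
        fmt = "%d"
    with open(path, "w") as fh:
        fh.write(f"ncols {n_cols}\n")
        fh.write(f"nrows {n_rows}\n")
        fh.write(f"xllcorner {x_ul:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {grid.cell_size:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        np.savetxt(fh, body, fmt=fmt)


def _read_ascii(path: Path, layer_kind: str) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    nodata = header.get("nodata_value", -9999.0)
    if np.all(values == np.round(values)) and np.abs(values).max(initial=0) < 2**31:
        values = values.astype(np.int64)
    return RasterGrid(values, cell_size=cell, origin=origin, nodata=nodata,
                      layer_kind=layer_kind)


def _write_tiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "nodata": grid.nodata,
        "layer_kind": grid.layer_kind,
    }
    tifffile.imwrite(path, grid.values, description=json.dumps(meta))


def _read_tiff(path: Path, layer_kind: str) -> RasterGrid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        desc = page.tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, json.JSONDecodeError):
                meta = {}
    return RasterGrid(
        values,
        cell_size=meta.get("cell_size", 30.0),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        nodata=meta.get("nodata", -9999.0),
        layer_kind=meta.get("layer_kind", layer_kind),
    )


def read_raster(path: str | Path, layer_kind: str = "generic") -> RasterGrid:
    """Read a raster; format chosen by extension (``.asc`` or ``.tif``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        return _read_ascii(path, layer_kind)
    if suffix in (".tif", ".tiff"):
        return _read_tiff(path, layer_kind)
    raise ValueError(f"unsupported raster format: {path.name}")


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a raster; format chosen by extension (``.asc`` or ``.tif``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".asc":
        _write_ascii(grid, path)
    elif suffix in (".tif", ".tiff"):
        _write_tiff(grid, path)
    else:
        raise ValueError(f"unsupported raster format: {path.name}")
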