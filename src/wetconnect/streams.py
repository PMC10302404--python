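"""The buffered-streams target layer and the riparian adjacency test.

Receiving waters are represented as the union of two sources: open-water
land-cover pixels (code 11), which give width to rivers wide enough to be
seen in imagery, and a rasterized stream-line grid, which catches channels
too narrow to map as water pixels.  The union is the "buffered streams"
layer: the target for both the riparian adjacency test and flowpath
termination.  Per-cell provenance (water pixel, stream line, or both) is
retained for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import RasterGrid, assert_aligned

__all__ = [
    "OPEN_WATER_CODE",
    "StreamMask",
    "build_buffered_streams",
    "is_riparian_adjacent",
]

OPEN_WATER_CODE = 11

#: provenance codes
PROV_NONE, PROV_WATER, PROV_LINE, PROV_BOTH = 0, 1, 2, 3


@dataclass
class StreamMask:
    """Buffered streams: boolean mask plus per-cell provenance."""

    provenance: RasterGrid  # uint8 grid of PROV_* codes

    @property
    def mask(self) -> np.ndarray:
        return self.provenance.values > 0

    @property
    def grid(self) -> RasterGrid:
        return self.provenance.like(self.mask, layer_kind="stream", nodata=0)

    def is_stream(self, row: int, col: int) -> bool:
        return bool(self.provenance.values[row, col] > 0)


def build_buffered_streams(
    landcover: RasterGrid,
    stream_raster: RasterGrid,
    water_code: int = OPEN_WATER_CODE,
) -> StreamMask:
    """Union of open-water pixels and rasterized stream lines.

    ``stream_raster`` is any grid where nonzero (and non-nodata) marks a
    stream-line cell; the exact rasterization dialect of the line source
    is up to the caller.
    """
    assert_aligned(landcover, stream_raster)
    water = landcover.values == water_code
    line = (stream_raster.values != 0) & ~stream_raster.nodata_mask()
    prov = np.zeros(landcover.shape, dtype=np.uint8)
    prov[water] = PROV_WATER
    prov[line] = np.where(water[line], PROV_BOTH, PROV_LINE)
    return StreamMask(landcover.like(prov, layer_kind="stream", nodata=0))


def is_riparian_adjacent(pour_point: tuple[int, int], streams: StreamMask) -> bool:
    """True iff the pour point is within one pixel of a buffered stream.

    "Within one pixel" counts both cardinal and ordinal directions, i.e.
    Chebyshev distance <= 1; a pour point lying *on* a stream/water cell
    (distance 0) counts as riparian — a wetland overlapping mapped water
    is maximally connected.
    """
    row, col = pour_point
    prov = streams.provenance.values
    if not streams.provenance.in_bounds(row, col):
        raise IndexError(f"pour point {pour_point} outside grid {prov.shape}")
    window = prov[max(row - 1, 0) : row + 2, max(col - 1, 0) : col + 2]
    return bool((window > 0).any())
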