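"""D8 hydrologic primitives: flow direction, accumulation, patch labeling.

The D8 convention routes every cell to exactly one of its eight neighbours.
Direction codes follow the powers-of-two convention used by the national
hydrography flow grids (and ESRI tools), fixed here in one place:

====  =========  ============
code  direction  (drow, dcol)
====  =========  ============
1     E          (0, +1)
2     SE         (+1, +1)
4     S          (+1, 0)
8     SW         (+1, -1)
16    W          (0, -1)
32    NW         (-1, -1)
64    N          (-1, 0)
128   NE         (-1, +1)
====  =========  ============

Flow accumulation counts, for each cell, the number of cells draining to it
through D8 links *including the cell itself* — the minimum value is 1.  Any
constant offset is rank-preserving and downstream logic (pour points) only
uses ranks, so this self-counting convention is benign; it keeps the
"highest accumulation pixel" rule well defined even on one-pixel wetlands.
"""

from __future__ import annotations

from collections import deque

import numpy as np
from scipy import ndimage

from .grid import RasterGrid

__all__ = [
    "D8_CODES",
    "D8_OFFSETS",
    "FDR_NODATA",
    "CycleError",
    "downstream_neighbor",
    "flow_accumulation",
    "d8_from_dem",
    "label_patches",
]

D8_CODES: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 64, 128)

D8_OFFSETS: dict[int, tuple[int, int]] = {
    1: (0, 1),
    2: (1, 1),
    4: (1, 0),
    8: (1, -1),
    16: (0, -1),
    32: (-1, -1),
    64: (-1, 0),
    128: (-1, 1),
}

#: nodata code used inside flow-direction grids (0 is never a valid D8 code)
FDR_NODATA = 0


class CycleError(ValueError):
    """A flow-direction grid contains a cycle; names one offending cell."""


def _valid_code(code: int) -> bool:
    return code in D8_OFFSETS


def downstream_neighbor(
    fdr: RasterGrid, cell: tuple[int, int]
) -> tuple[int, int] | None:
    """The single cell downstream of ``cell``, or ``None``.

    Returns ``None`` when the cell's code is nodata/invalid or the step
    would leave the grid.  Raises ``IndexError`` for an out-of-bounds cell.
    """
    row, col = cell
    if not fdr.in_bounds(row, col):
        raise IndexError(f"cell {cell} outside grid of shape {fdr.shape}")
    code = int(fdr.values[row, col])
    if not _valid_code(code):
        return None
    drow, dcol = D8_OFFSETS[code]
    nxt = (row + drow, col + dcol)
    if not fdr.in_bounds(*nxt):
        return None
    return nxt


def _downstream_index_arrays(fdr: RasterGrid):
    """Vector form of downstream links: flat index of the receiver, -1 if none."""
    n_rows, n_cols = fdr.shape
    vals = fdr.values
    down = np.full(vals.size, -1, dtype=np.int64)
    valid = np.zeros(vals.size, dtype=bool)
    flat = vals.ravel()
    for code, (drow, dcol) in D8_OFFSETS.items():
        sel = np.flatnonzero(flat == code)
        if sel.size == 0:
            continue
        valid[sel] = True
        rows, cols = np.unravel_index(sel, (n_rows, n_cols))
        nr, nc = rows + drow, cols + dcol
        inside = (nr >= 0) & (nr < n_rows) & (nc >= 0) & (nc < n_cols)
        down[sel[inside]] = nr[inside] * n_cols + nc[inside]
    return down, valid


def flow_accumulation(fdr: RasterGrid) -> RasterGrid:
    """Flow accumulation (cells draining to each cell, self included).

    Every cell's value equals the number of cells whose downstream walk
    passes through it, itself included, so the minimum is 1.  Cells with a
    nodata direction code act as sinks: they accumulate inflow but pass
    nothing on (pits and outlets trap what reaches them).  The direction
    grid must be acyclic; a cycle raises :class:`CycleError` naming one
    cell on the cycle.
    """
    down, valid = _downstream_index_arrays(fdr)
    n_rows, n_cols = fdr.shape
    has_link = down >= 0  # off-grid steps and sink cells pass nothing on

    acc = np.ones(valid.size, dtype=np.int64)
    indeg = np.zeros(valid.size, dtype=np.int64)
    np.add.at(indeg, down[has_link], 1)

    queue = deque(np.flatnonzero(indeg == 0).tolist())
    processed = 0
    while queue:
        u = queue.popleft()
        processed += 1
        if has_link[u]:
            v = down[u]
            acc[v] += acc[u]
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    if processed != valid.size:
        stuck = int(np.flatnonzero(indeg > 0)[0])
        cell = np.unravel_index(stuck, (n_rows, n_cols))
        raise CycleError(
            f"flow-direction grid has a cycle through cell {tuple(map(int, cell))}"
        )
    return fdr.like(
        acc.reshape(n_rows, n_cols), layer_kind="accumulation", nodata=-1
    )


def d8_from_dem(dem: RasterGrid) -> RasterGrid:
    """Steepest-descent D8 directions from an elevation grid.

    Gradient to each neighbour is elevation drop divided by centre distance
    (``cell_size`` for cardinal, ``cell_size * sqrt(2)`` for diagonal).
    Ties break in fixed code order 1, 2, 4, ..., 128.  Cells with no
    strictly lower neighbour (pits, flats) become nodata; the synthetic
    terrain generator is responsible for supplying pit-free surfaces.
    """
    z = np.asarray(dem.values, dtype=float)
    n_rows, n_cols = z.shape
    padded = np.full((n_rows + 2, n_cols + 2), np.inf)
    padded[1:-1, 1:-1] = z

    slopes = np.empty((len(D8_CODES), n_rows, n_cols))
    for i, code in enumerate(D8_CODES):
        drow, dcol = D8_OFFSETS[code]
        neighbor = padded[1 + drow : 1 + drow + n_rows, 1 + dcol : 1 + dcol + n_cols]
        dist = dem.cell_size * (np.sqrt(2.0) if drow and dcol else 1.0)
        slopes[i] = (z - neighbor) / dist

    best = np.argmax(slopes, axis=0)  # first max in code order wins ties
    best_slope = np.take_along_axis(slopes, best[None], axis=0)[0]
    codes = np.array(D8_CODES)[best]
    codes = np.where(best_slope > 0, codes, FDR_NODATA)
    return dem.like(codes.astype(np.int32), layer_kind="flowdir", nodata=FDR_NODATA)


def label_patches(mask: RasterGrid, connectivity: int = 8) -> RasterGrid:
    """Label connected true-cells with dense positive integers.

    Default connectivity is 8 (diagonal neighbours join a patch), matching
    the "ordinal and cardinal directions" adjacency used throughout the
    classification; 4-connectivity is kept as an option.  False cells get
    label 0.
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    structure = (
        np.ones((3, 3), dtype=int)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, _ = ndimage.label(np.asarray(mask.values, dtype=bool), structure=structure)
    return mask.like(labels.astype(np.int32), layer_kind="label", nodata=-1)
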