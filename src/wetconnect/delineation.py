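"""Wetland unit delineation.

Wetland pixels (woody, code 90, and emergent herbaceous, code 95, in the
national land-cover coding; the two are merged and their identity
discarded) are grouped into contiguous patches, then subdivided wherever a
patch crosses a catchment boundary.  Each resulting (patch, catchment)
piece is a hydrologically distinct *wetland unit* with its own WetId and a
single pour point: the unit pixel with the highest flow accumulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .d8 import label_patches
from .grid import RasterGrid, assert_aligned

__all__ = [
    "WETLAND_CODES",
    "WetlandUnit",
    "PourPointError",
    "extract_wetland_mask",
    "subdivide_by_catchment",
    "find_pour_point",
    "compute_area",
    "delineate",
    "units_to_label_grid",
]

#: land-cover codes treated as wetland (woody / emergent herbaceous)
WETLAND_CODES: tuple[int, ...] = (90, 95)


class PourPointError(ValueError):
    """No pour point can be determined (accumulation nodata over the unit)."""


@dataclass
class WetlandUnit:
    """A catchment-subdivided wetland with a unique (per run) WetId."""

    wet_id: int
    patch_id: int
    catchment_id: int | None
    pixels: list[tuple[int, int]]
    area_km2: float = 0.0
    pour_point: tuple[int, int] | None = None
    #: routed straight to Unclassified (nodata catchment, no pour point, ...)
    flag_unclassified: bool = False
    flag_reason: str = ""

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("a wetland unit must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def extract_wetland_mask(
    landcover: RasterGrid, wetland_codes: tuple[int, ...] = WETLAND_CODES
) -> RasterGrid:
    """Boolean wetland mask from the land-cover grid."""
    mask = np.isin(landcover.values, wetland_codes)
    return landcover.like(mask, layer_kind="label", nodata=0)


def subdivide_by_catchment(
    patch_labels: RasterGrid, catchments: RasterGrid
) -> list[WetlandUnit]:
    """Split patches on catchment boundaries into wetland units.

    One unit per non-empty (patch_id, catchment_id) pair; units partition
    the patch pixels exactly.  WetIds are assigned densely from 1 in
    (patch_id, catchment_id) lexicographic order, nodata-catchment groups
    ordered last within their patch.  Wetland pixels on a nodata catchment
    (for example at the grid edge) are retained as a unit flagged for
    Unclassified rather than dropped.
    """
    assert_aligned(patch_labels, catchments)
    labels = patch_labels.values
    cats = catchments.values
    cat_nodata = catchments.nodata

    groups: dict[tuple[int, float], list[tuple[int, int]]] = {}
    rows, cols = np.nonzero(labels > 0)
    for row, col in zip(rows.tolist(), cols.tolist()):
        patch = int(labels[row, col])
        cat = cats[row, col]
        key_cat = math.inf if cat == cat_nodata else int(cat)
        groups.setdefault((patch, key_cat), []).append((row, col))

    units: list[WetlandUnit] = []
    for wet_id, (patch, key_cat) in enumerate(sorted(groups), start=1):
        nodata_cat = key_cat == math.inf
        units.append(
            WetlandUnit(
                wet_id=wet_id,
                patch_id=patch,
                catchment_id=None if nodata_cat else int(key_cat),
                pixels=sorted(groups[(patch, key_cat)]),
                flag_unclassified=nodata_cat,
                flag_reason="no_catchment" if nodata_cat else "",
            )
        )
    return units


def find_pour_point(unit: WetlandUnit, accumulation: RasterGrid) -> tuple[int, int]:
    """The unit pixel with the highest flow accumulation.

    Ties break to the smallest (row, col) in row-major order, which makes
    pour points deterministic across runs and iteration orders.  A unit
    whose pixels are all nodata in the accumulation grid has no defined
    outlet and raises :class:`PourPointError`.
    """
    best: tuple[int, int] | None = None
    best_val = None
    for row, col in sorted(unit.pixels):
        if accumulation.is_nodata(row, col):
            continue
        val = accumulation.values[row, col]
        if best_val is None or val > best_val:
            best, best_val = (row, col), val
    if best is None:
        raise PourPointError(
            f"wetland unit {unit.wet_id}: accumulation is nodata over all pixels"
        )
    return best


def compute_area(n_pixels: int, cell_size: float) -> float:
    """Area in km^2 of ``n_pixels`` square pixels of edge ``cell_size`` metres."""
    if n_pixels <= 0:
        raise ValueError("area requires at least one pixel")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    return n_pixels * cell_size**2 / 1e6


def delineate(
    landcover: RasterGrid,
    catchments: RasterGrid,
    accumulation: RasterGrid,
    connectivity: int = 8,
) -> list[WetlandUnit]:
    """Full delineation: mask -> patches -> subdivision -> pour points -> areas."""
    assert_aligned(landcover, catchments, accumulation)
    mask = extract_wetland_mask(landcover)
    patches = label_patches(mask, connectivity=connectivity)
    units = subdivide_by_catchment(patches, catchments)
    for unit in units:
        unit.area_km2 = compute_area(unit.n_pixels, landcover.cell_size)
        try:
            unit.pour_point = find_pour_point(unit, accumulation)
        except PourPointError:
            unit.pour_point = None
            unit.flag_unclassified = True
            unit.flag_reason = unit.flag_reason or "no_pour_point"
    return units


def units_to_label_grid(units: list[WetlandUnit], template: RasterGrid) -> RasterGrid:
    """Grid of WetIds (0 = not wetland), for output and path bookkeeping."""
    out = np.zeros(template.shape, dtype=np.int32)
    for unit in units:
        for row, col in unit.pixels:
            out[row, col] = unit.wet_id
    return template.like(out, layer_kind="label", nodata=0)
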