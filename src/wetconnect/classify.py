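"""Flowpath tracing, soil aggregation and the four-class assignment.

The classification decision flow is:

1. If the wetland's pour point is within one pixel of a buffered stream,
   the wetland is **Riparian** — soils are never consulted.
2. Otherwise a D8 flowpath is traced from the pour point downhill until it
   would step onto a buffered-stream cell (crossing catchment boundaries
   and other wetlands freely).  A path that fails to reach a stream
   (exits the grid, hits a nodata direction, loops, or exhausts the step
   budget) makes the wetland **Unclassified**.
3. The minimum saturated hydraulic conductivity (Ksat, cm/h) over the path
   is compared with a permeability threshold (default 5.08 cm/h, the
   boundary between very fine sandy loams and sandy loams).  The minimum
   is used because the least permeable cell limits subsurface flow.
   Impermeable (min Ksat below the threshold) -> **NRDeep**.
4. Permeable paths split on the length-weighted majority soil drainage
   class: poorly drained -> **NRShw** (shallow subsurface flow,
   saturation-excess overland flow), well drained -> **NRMid** (mid-depth
   subsurface flow, infiltration-excess overland flow).  Majority, not
   minimum, because drainage differentiates subsurface flow regimes
   rather than limiting them.

Seven-category NRCS drainage codes group as: well drained = {excessively,
somewhat excessively, well, moderately well drained} (codes 1-4), poorly
drained = {somewhat poorly, poorly, very poorly drained} (codes 5-7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .delineation import WetlandUnit
from .grid import RasterGrid, assert_aligned
from .d8 import D8_OFFSETS, downstream_neighbor
from .streams import StreamMask, is_riparian_adjacent

__all__ = [
    "ConnectivityClass",
    "Terminal",
    "Flowpath",
    "FlowpathSoil",
    "DEFAULT_KSAT_THRESHOLD",
    "WELL_DRAINED_CODES",
    "POORLY_DRAINED_CODES",
    "DrainageCodeError",
    "trace_flowpath",
    "path_min_ksat",
    "path_majority_drainage",
    "classify_wetland",
    "classify_all",
]


class ConnectivityClass(str, Enum):
    """The four wetland hydrologic connectivity classes plus Unclassified."""

    RIPARIAN = "Riparian"
    NRSHW = "NRShw"
    NRMID = "NRMid"
    NRDEEP = "NRDeep"
    UNCLASSIFIED = "Unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Terminal(str, Enum):
    """How a flowpath ended."""

    REACHED_STREAM = "reached_stream"
    EXITED_GRID = "exited_grid"
    HIT_NODATA = "hit_nodata"
    LOOP_DETECTED = "loop_detected"
    MAX_STEPS = "max_steps"
    NOT_TRACED = "not_traced"  # riparian / flagged units: no trace attempted


#: Ksat cut-off (cm/h) between permeable and impermeable flowpath soils
DEFAULT_KSAT_THRESHOLD = 5.08

WELL_DRAINED_CODES = frozenset({1, 2, 3, 4})
POORLY_DRAINED_CODES = frozenset({5, 6, 7})


class DrainageCodeError(ValueError):
    """A drainage cell holds a code outside the seven NRCS categories."""


@dataclass
class Flowpath:
    """An ordered walk of land cells from a pour point toward a stream."""

    cells: list[tuple[int, int]]
    terminal: Terminal
    #: distance of each inter-cell step (len == len(cells) - 1)
    step_lengths: list[float] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.terminal is Terminal.REACHED_STREAM

    @property
    def length_m(self) -> float:
        return float(sum(self.step_lengths))

    def cell_weights(self, cell_size: float) -> list[float]:
        """Per-cell length contribution: the pour-point cell contributes one
        cell size, every later cell the length of the step that reached it."""
        return [cell_size] + list(self.step_lengths)


@dataclass
class FlowpathSoil:
    """Soil attributes aggregated along one flowpath."""

    min_ksat: float | None
    drainage_majority: str | None  # "poorly_drained" | "well_drained" | None
    ksat_n_valid: int = 0
    drainage_n_valid: int = 0


def trace_flowpath(
    pour_point: tuple[int, int],
    fdr: RasterGrid,
    streams: StreamMask,
    max_steps: int | None = None,
) -> Flowpath:
    """Walk D8 links from ``pour_point`` until a stream cell is next.

    The walk stops *before* stepping onto a buffered-stream cell, so the
    path holds land cells only (the pour point is always included, even for
    a length-1 path).  Catchment boundaries are crossed freely.  All
    failure modes are encoded in ``terminal`` rather than raised:
    ``exited_grid`` (next step leaves the grid), ``hit_nodata`` (nodata
    direction code), ``loop_detected``, ``max_steps``.  The default step
    budget is the grid cell count, which makes non-termination impossible.
    """
    if max_steps is None:
        max_steps = fdr.values.size
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")

    row, col = pour_point
    if not fdr.in_bounds(row, col):
        raise IndexError(f"pour point {pour_point} outside grid {fdr.shape}")

    cells = [(row, col)]
    steps: list[float] = []
    visited = {(row, col)}
    if streams.is_stream(row, col):
        # degenerate start: the outlet already sits on mapped water
        return Flowpath(cells, Terminal.REACHED_STREAM, steps)

    current = (row, col)
    diag = fdr.cell_size * math.sqrt(2.0)
    for _ in range(max_steps):
        code = int(fdr.values[current])
        nxt = downstream_neighbor(fdr, current)
        if nxt is None:
            # no successor: either the code is nodata/invalid or the step
            # would leave the grid
            if code not in D8_OFFSETS:
                return Flowpath(cells, Terminal.HIT_NODATA, steps)
            return Flowpath(cells, Terminal.EXITED_GRID, steps)
        if streams.is_stream(*nxt):
            return Flowpath(cells, Terminal.REACHED_STREAM, steps)
        if nxt in visited:
            return Flowpath(cells, Terminal.LOOP_DETECTED, steps)
        drow = abs(nxt[0] - current[0])
        dcol = abs(nxt[1] - current[1])
        steps.append(diag if drow and dcol else fdr.cell_size)
        cells.append(nxt)
        visited.add(nxt)
        current = nxt
    return Flowpath(cells, Terminal.MAX_STEPS, steps)


def path_min_ksat(path: Flowpath, ksat: RasterGrid) -> float | None:
    """Minimum Ksat over non-nodata path cells; ``None`` if none valid."""
    vals = [
        float(ksat.values[row, col])
        for row, col in path.cells
        if not ksat.is_nodata(row, col)
    ]
    return min(vals) if vals else None


def path_majority_drainage(path: Flowpath, drainage: RasterGrid) -> str | None:
    """Length-weighted majority drainage group along the path.

    Each cell contributes its step length (the pour-point cell contributes
    one cell size); the group with the greater total length wins, and an
    exact tie goes to ``poorly_drained`` (conservative toward the shallower,
    more frequently surface-connected class).  ``None`` when no valid cell.
    """
    weights = path.cell_weights(drainage.cell_size)
    poor = well = 0.0
    n_valid = 0
    for (row, col), weight in zip(path.cells, weights):
        if drainage.is_nodata(row, col):
            continue
        code = int(drainage.values[row, col])
        if code in POORLY_DRAINED_CODES:
            poor += weight
        elif code in WELL_DRAINED_CODES:
            well += weight
        else:
            raise DrainageCodeError(
                f"unknown drainage code {code} at cell {(row, col)}"
            )
        n_valid += 1
    if n_valid == 0:
        return None
    return "poorly_drained" if poor >= well else "well_drained"


def aggregate_path_soil(
    path: Flowpath, ksat: RasterGrid, drainage: RasterGrid
) -> FlowpathSoil:
    """Both soil aggregations plus valid-cell counts for one path."""
    min_ksat = path_min_ksat(path, ksat)
    majority = path_majority_drainage(path, drainage)
    n_ksat = sum(0 if ksat.is_nodata(r, c) else 1 for r, c in path.cells)
    n_drain = sum(0 if drainage.is_nodata(r, c) else 1 for r, c in path.cells)
    return FlowpathSoil(min_ksat, majority, n_ksat, n_drain)


def classify_wetland(
    adjacent: bool,
    soil: FlowpathSoil | None,
    threshold: float = DEFAULT_KSAT_THRESHOLD,
    path_ok: bool = True,
) -> ConnectivityClass:
    """Assign one connectivity class from the decision flow.

    Adjacency decides first (Riparian, soils ignored); then path failure or
    missing soils give Unclassified; then min Ksat below the threshold
    gives NRDeep; permeable paths split on drainage majority.  Ksat exactly
    at the threshold counts as permeable (the source rules state only
    strict inequalities on both sides; equality is resolved here).
    """
    if adjacent:
        return ConnectivityClass.RIPARIAN
    if not path_ok or soil is None or soil.min_ksat is None:
        return ConnectivityClass.UNCLASSIFIED
    if soil.min_ksat < threshold:
        return ConnectivityClass.NRDEEP
    if soil.drainage_majority == "poorly_drained":
        return ConnectivityClass.NRSHW
    if soil.drainage_majority == "well_drained":
        return ConnectivityClass.NRMID
    return ConnectivityClass.UNCLASSIFIED


def classify_all(
    units: list[WetlandUnit],
    fdr: RasterGrid,
    streams: StreamMask,
    ksat: RasterGrid,
    drainage: RasterGrid,
    wet_labels: RasterGrid | None = None,
    threshold: float = DEFAULT_KSAT_THRESHOLD,
    max_steps: int | None = None,
) -> pd.DataFrame:
    """Classify every wetland unit; one record per unit, never aborting.

    Per-unit failures (no pour point, failed trace, missing soils) degrade
    that unit to Unclassified with the failure encoded in ``terminal`` /
    ``flag_reason``.  ``wet_labels`` (WetId grid) enables recording the
    downstream wetlands each flowpath crosses, in path order.
    """
    assert_aligned(fdr, streams.provenance, ksat, drainage)
    records = []
    for unit in units:
        rec = {
            "wet_id": unit.wet_id,
            "patch_id": unit.patch_id,
            "catchment_id": unit.catchment_id,
            "pixel_count": unit.n_pixels,
            "area_km2": unit.area_km2,
            "adjacent": False,
            "connectivity_class": ConnectivityClass.UNCLASSIFIED.value,
            "terminal": Terminal.NOT_TRACED.value,
            "min_ksat": np.nan,
            "drainage_majority": "",
            "path_length_m": np.nan,
            "n_path_cells": 0,
            "downstream_wet_ids": "",
            "flag_reason": unit.flag_reason,
        }
        if unit.flag_unclassified or unit.pour_point is None:
            records.append(rec)
            continue

        adjacent = is_riparian_adjacent(unit.pour_point, streams)
        rec["adjacent"] = adjacent
        if adjacent:
            rec["connectivity_class"] = ConnectivityClass.RIPARIAN.value
            records.append(rec)
            continue

        path = trace_flowpath(unit.pour_point, fdr, streams, max_steps=max_steps)
        rec["terminal"] = path.terminal.value
        rec["path_length_m"] = path.length_m
        rec["n_path_cells"] = len(path.cells)
        if wet_labels is not None:
            seen: list[int] = []
            for row, col in path.cells[1:]:
                wid = int(wet_labels.values[row, col])
                if wid and wid != unit.wet_id and wid not in seen:
                    seen.append(wid)
            rec["downstream_wet_ids"] = ";".join(str(w) for w in seen)

        if not path.ok:
            records.append(rec)
            continue

        soil = aggregate_path_soil(path, ksat, drainage)
        if soil.min_ksat is not None:
            rec["min_ksat"] = soil.min_ksat
        rec["drainage_majority"] = soil.drainage_majority or ""
        rec["connectivity_class"] = classify_wetland(
            adjacent=False, soil=soil, threshold=threshold, path_ok=True
        ).value
        records.append(rec)

    columns = [
        "wet_id", "patch_id", "catchment_id", "pixel_count", "area_km2",
        "adjacent", "connectivity_class", "terminal", "min_ksat",
        "drainage_majority", "path_length_m", "n_path_cells",
        "downstream_wet_ids", "flag_reason",
    ]
    return pd.DataFrame(records, columns=columns)
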