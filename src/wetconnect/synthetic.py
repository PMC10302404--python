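"""Synthetic landscape bundles with known ground-truth connectivity classes.

The generator emulates every input layer the classification pipeline
needs — terrain, D8 flow direction and accumulation, streams, catchments,
land cover with wetlands, and flowpath soils — on a small grid with an
internally consistent hydrology, and records the class each wetland was
engineered to receive.  Its central postcondition: running the real
pipeline on a bundle reproduces the recorded truth table exactly.

Terrain is a V-shaped valley: a plane tilted toward the east combined
with a cross-slope toward a central valley row, plus bounded seeded
noise.  This guarantees (after a pit check with retries) a pit-free
surface whose D8 field converges on an eastward-flowing channel, without
implementing DEM conditioning.  Streams are accumulation-thresholded
channel cells; catchments are derived by chunking the channel into
segments and walking every land cell to the segment it first reaches.

Soil recipes paint only flowpath-relevant cells and leave neutral values
elsewhere (Ksat 10 cm/h, well drained), so each wetland's class is
controlled by its own recipe:

* ``Riparian``  — anchor within one pixel of the channel; soils untouched.
* ``NRShw``     — path cells painted poorly drained (code 6), Ksat left 10.
* ``NRMid``     — path cells painted well drained (code 3), Ksat left 10.
* ``NRDeep``    — one mid-path cell painted Ksat 1.0 cm/h (< 5.08).
* ``Unclassified`` — path cells' Ksat and drainage painted nodata.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .classify import ConnectivityClass, classify_all, trace_flowpath
from .d8 import FDR_NODATA, d8_from_dem, downstream_neighbor, flow_accumulation
from .delineation import delineate, find_pour_point, units_to_label_grid, WetlandUnit
from .grid import RasterGrid
from .streams import OPEN_WATER_CODE, StreamMask, build_buffered_streams

__all__ = [
    "GenerationError",
    "PlacementError",
    "ScenarioError",
    "ScenarioSpec",
    "WetlandIntent",
    "ScenarioBundle",
    "generate_terrain",
    "derive_hydrology",
    "place_wetland",
    "generate_catchments",
    "build_scenario",
]

LAND_CODE = 41  # generic upland land cover
WETLAND_CODE = 95
SOIL_NODATA = -9999.0
CAT_NODATA = -1


class GenerationError(RuntimeError):
    """Pit-free terrain could not be generated within the retry budget."""


class PlacementError(RuntimeError):
    """A wetland intent is unachievable at its anchor."""


class ScenarioError(RuntimeError):
    """The pipeline did not reproduce the generator's truth table."""


@dataclass
class WetlandIntent:
    """One wetland to engineer: where, how big, and which class."""

    intended_class: ConnectivityClass
    anchor: tuple[int, int] | None = None  # auto-placed when None
    n_pixels: int = 4


@dataclass
class ScenarioSpec:
    """Everything needed to regenerate a bundle bit-identically."""

    seed: int
    shape: tuple[int, int] = (40, 60)
    cell_size: float = 30.0
    relief: float = 60.0
    stream_threshold: int | None = None  # default: 4x the number of rows
    noise_amplitude: float = 0.002  # fraction of relief
    n_catchments: int = 3
    wetlands: list[WetlandIntent] | None = None  # default: one of each class


@dataclass
class ScenarioBundle:
    """All aligned grids plus the recorded ground truth."""

    spec: ScenarioSpec
    dem: RasterGrid
    landcover: RasterGrid
    fdr: RasterGrid
    accumulation: RasterGrid
    streamlines: RasterGrid
    catchments: RasterGrid
    ksat: RasterGrid
    drainage: RasterGrid
    truth: pd.DataFrame  # wet_id, anchor_row, anchor_col, intended_class
    topology: pd.DataFrame  # from_id, to_id
    catchment_areas: pd.DataFrame  # catchment_id, area_km2

    def stream_mask(self) -> StreamMask:
        return build_buffered_streams(self.landcover, self.streamlines)

    def grids(self) -> dict[str, RasterGrid]:
        return {
            "dem": self.dem,
            "landcover": self.landcover,
            "fdr": self.fdr,
            "accumulation": self.accumulation,
            "streamlines": self.streamlines,
            "catchments": self.catchments,
            "ksat": self.ksat,
            "drainage": self.drainage,
        }


# ---------------------------------------------------------------------------
# terrain and hydrology
# ---------------------------------------------------------------------------

def generate_terrain(
    seed: int,
    shape: tuple[int, int] = (40, 60),
    relief: float = 60.0,
    noise_amplitude: float = 0.002,
    cell_size: float = 30.0,
    max_retries: int = 10,
) -> RasterGrid:
    """V-valley terrain: eastward tilt + cross-slope to a central row.

    ``noise_amplitude`` is the half-range of the added uniform noise as a
    fraction of ``relief``.  The surface is regenerated with fresh noise
    until its interior is pit-free (every non-edge cell has a strictly
    lower neighbour), raising :class:`GenerationError` after
    ``max_retries`` failures.  Identical seeds give identical grids.
    """
    n_rows, n_cols = shape
    if n_rows < 4 or n_cols < 4:
        raise ValueError("terrain requires at least a 4x4 grid")
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    valley_row = n_rows // 2
    base = (n_cols - 1 - cols) + 4.0 * np.abs(rows - valley_row)
    base = base * (relief / base.max())

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        noise = rng.uniform(-1.0, 1.0, size=shape) * noise_amplitude * relief
        dem = RasterGrid(base + noise, cell_size=cell_size, layer_kind="dem",
                         nodata=np.nan)
        fdr = d8_from_dem(dem)
        interior = fdr.values[1:-1, 1:-1]
        if not (interior == FDR_NODATA).any():
            return dem
    raise GenerationError(
        f"no pit-free terrain in {max_retries} tries "
        f"(noise_amplitude={noise_amplitude} too large for this relief)"
    )


def derive_hydrology(
    dem: RasterGrid, stream_threshold: int
) -> tuple[RasterGrid, RasterGrid, RasterGrid]:
    """Flow direction, flow accumulation and thresholded stream cells."""
    fdr = d8_from_dem(dem)
    acc = flow_accumulation(fdr)
    stream = (acc.values != acc.nodata) & (acc.values >= stream_threshold)
    streamlines = dem.like(stream.astype(np.int8), layer_kind="stream", nodata=-1)
    return fdr, acc, streamlines


# ---------------------------------------------------------------------------
# wetland placement
# ---------------------------------------------------------------------------

def _chebyshev_distance_to(mask: np.ndarray) -> np.ndarray:
    """Chebyshev (chessboard) distance of every cell to the nearest True cell."""
    if not mask.any():
        return np.full(mask.shape, np.iinfo(np.int32).max)
    return ndimage.distance_transform_cdt(~mask, metric="chessboard")


def grow_region(
    anchor: tuple[int, int],
    n_pixels: int,
    allowed: np.ndarray,
) -> list[tuple[int, int]]:
    """Grow an 8-connected region of ``n_pixels`` cells from ``anchor``.

    Breadth-first over allowed cells, visiting neighbours in fixed row-major
    order for determinism.  Raises :class:`PlacementError` when the region
    cannot reach the requested size.
    """
    n_rows, n_cols = allowed.shape
    if not allowed[anchor]:
        raise PlacementError(f"anchor {anchor} is not an allowed cell")
    region = [anchor]
    taken = {anchor}
    frontier = [anchor]
    while len(region) < n_pixels and frontier:
        nxt: list[tuple[int, int]] = []
        for row, col in frontier:
            for drow in (-1, 0, 1):
                for dcol in (-1, 0, 1):
                    if drow == 0 and dcol == 0:
                        continue
                    cell = (row + drow, col + dcol)
                    if (
                        0 <= cell[0] < n_rows
                        and 0 <= cell[1] < n_cols
                        and cell not in taken
                        and allowed[cell]
                    ):
                        taken.add(cell)
                        nxt.append(cell)
                        region.append(cell)
                        if len(region) == n_pixels:
                            return region
        frontier = nxt
    if len(region) < n_pixels:
        raise PlacementError(
            f"only {len(region)} of {n_pixels} pixels available at anchor {anchor}"
        )
    return region


def place_wetland(
    landcover: RasterGrid,
    fdr: RasterGrid,
    accumulation: RasterGrid,
    streams: StreamMask,
    ksat: RasterGrid,
    drainage: RasterGrid,
    anchor: tuple[int, int],
    n_pixels: int,
    intended_class: ConnectivityClass,
    claimed: set[tuple[int, int]] | None = None,
) -> dict:
    """Grow one wetland at ``anchor`` and paint soils for its intended class.

    Mutates ``landcover`` (wetland pixels to code 95) and, along the traced
    flowpath, ``ksat`` / ``drainage`` according to the class recipe.
    ``claimed`` is a registry of cells already used by other wetlands or
    their painted flowpaths; any collision raises :class:`PlacementError`
    so recipes can never contaminate each other.  Returns the truth row.
    """
    claimed = claimed if claimed is not None else set()
    stream_dist = _chebyshev_distance_to(streams.mask)
    riparian = intended_class is ConnectivityClass.RIPARIAN

    if riparian:
        if stream_dist[anchor] > 1:
            raise PlacementError(f"riparian anchor {anchor} not adjacent to a stream")
    elif stream_dist[anchor] < 2:
        raise PlacementError(
            f"non-riparian anchor {anchor} within one pixel of a stream"
        )

    # riparian wetlands grow inside the one-pixel stream buffer so the pour
    # point (wherever accumulation peaks) stays adjacent; non-riparian
    # wetlands keep every pixel at least two cells away
    allowed = (landcover.values == LAND_CODE) & ~streams.mask
    if riparian:
        allowed &= stream_dist <= 1
    else:
        allowed &= stream_dist >= 2
    for cell in claimed:
        allowed[cell] = False
    pixels = grow_region(anchor, n_pixels, allowed)

    unit = WetlandUnit(wet_id=0, patch_id=0, catchment_id=0, pixels=pixels)
    pour = find_pour_point(unit, accumulation)
    adjacent = stream_dist[pour] <= 1

    if riparian:
        if not adjacent:
            raise PlacementError(f"riparian intent at {anchor}: pour point {pour} "
                                 "not stream-adjacent")
    else:
        if adjacent:
            raise PlacementError(f"non-riparian intent at {anchor}: pour point "
                                 f"{pour} is stream-adjacent")
        path = trace_flowpath(pour, fdr, streams)
        if not path.ok:
            raise PlacementError(
                f"intent at {anchor}: flowpath terminal {path.terminal.value}"
            )
        path_cells = path.cells
        if set(path_cells) & claimed:
            raise PlacementError(f"intent at {anchor}: flowpath crosses claimed cells")
        if intended_class is ConnectivityClass.NRSHW:
            for cell in path_cells:
                drainage.values[cell] = 6  # poorly drained
        elif intended_class is ConnectivityClass.NRMID:
            for cell in path_cells:
                drainage.values[cell] = 3  # well drained
        elif intended_class is ConnectivityClass.NRDEEP:
            mid = path_cells[len(path_cells) // 2]
            ksat.values[mid] = 1.0  # impermeable spot on the path
        elif intended_class is ConnectivityClass.UNCLASSIFIED:
            for cell in path_cells:
                ksat.values[cell] = ksat.nodata
                drainage.values[cell] = int(drainage.nodata)
        else:  # pragma: no cover - exhaustive enum
            raise ValueError(f"unknown intent {intended_class}")
        claimed.update(path_cells)

    for cell in pixels:
        landcover.values[cell] = WETLAND_CODE
    claimed.update(pixels)
    return {
        "anchor_row": anchor[0],
        "anchor_col": anchor[1],
        "intended_class": intended_class.value,
        "n_pixels": n_pixels,
    }


# ---------------------------------------------------------------------------
# catchments
# ---------------------------------------------------------------------------

def generate_catchments(
    streamlines: RasterGrid,
    fdr: RasterGrid,
    n_catchments: int,
) -> tuple[RasterGrid, pd.DataFrame, pd.DataFrame]:
    """Segment the stream and assign every cell to the segment it drains to.

    Stream cells are ordered along the flow (topologically) and chunked
    into ``n_catchments`` contiguous segments.  Each cell's catchment is
    the segment of the first stream cell its D8 walk reaches; cells whose
    walk leaves the grid or dies on nodata get catchment nodata.  The
    returned topology (from_id -> to_id, NaN at outlets) follows stream
    flow and is acyclic by construction.
    """
    stream_cells = [tuple(map(int, rc)) for rc in np.argwhere(streamlines.values == 1)]
    if n_catchments < 1 or n_catchments > len(stream_cells):
        raise ValueError(
            f"n_catchments={n_catchments} not in [1, {len(stream_cells)}] "
            "(number of stream cells)"
        )
    stream_set = set(stream_cells)

    # topological order of the stream subgraph (edges follow D8 within streams)
    succ: dict[tuple[int, int], tuple[int, int]] = {}
    indeg = {cell: 0 for cell in stream_cells}
    for cell in stream_cells:
        nxt = downstream_neighbor(fdr, cell)
        if nxt is not None and nxt in stream_set:
            succ[cell] = nxt
            indeg[nxt] += 1
    order: list[tuple[int, int]] = []
    frontier = sorted(c for c in stream_cells if indeg[c] == 0)
    queue = deque(frontier)
    while queue:
        cell = queue.popleft()
        order.append(cell)
        nxt = succ.get(cell)
        if nxt is not None:
            indeg[nxt] -= 1
            if indeg[nxt] == 0:
                queue.append(nxt)
    if len(order) != len(stream_cells):
        raise ValueError("stream subgraph is not acyclic")

    seg_of: dict[tuple[int, int], int] = {}
    bounds = np.linspace(0, len(order), n_catchments + 1).astype(int)
    for seg_idx in range(n_catchments):
        for cell in order[bounds[seg_idx] : bounds[seg_idx + 1]]:
            seg_of[cell] = seg_idx + 1

    # walk every cell to its first stream cell, with memoisation
    n_rows, n_cols = fdr.shape
    catchment = np.full((n_rows, n_cols), CAT_NODATA, dtype=np.int32)
    memo: dict[tuple[int, int], int] = {}

    def resolve(cell: tuple[int, int]) -> int:
        trail: list[tuple[int, int]] = []
        current: tuple[int, int] | None = cell
        result = CAT_NODATA
        seen_on_trail = set()
        while current is not None:
            if current in memo:
                result = memo[current]
                break
            if current in seg_of:
                result = seg_of[current]
                break
            if current in seen_on_trail:
                result = CAT_NODATA  # defensive: cycle off-stream
                break
            trail.append(current)
            seen_on_trail.add(current)
            current = downstream_neighbor(fdr, current)
        for visited in trail:
            memo[visited] = result
        return result

    for row in range(n_rows):
        for col in range(n_cols):
            catchment[row, col] = resolve((row, col))

    cat_grid = fdr.like(catchment, layer_kind="catchment", nodata=CAT_NODATA)

    # segment topology: edge where a stream cell's successor lies in another segment
    edges = set()
    outlets = set(range(1, n_catchments + 1))
    for cell, nxt in succ.items():
        a, b = seg_of[cell], seg_of[nxt]
        if a != b:
            edges.add((a, b))
            outlets.discard(a)
    topo_rows = [{"from_id": a, "to_id": b} for a, b in sorted(edges)]
    for seg in sorted(outlets):
        topo_rows.append({"from_id": seg, "to_id": np.nan})
    topology = pd.DataFrame(topo_rows, columns=["from_id", "to_id"])

    ids, cell_counts = np.unique(catchment[catchment != CAT_NODATA], return_counts=True)
    areas = pd.DataFrame({
        "catchment_id": ids.astype(int),
        "area_km2": cell_counts * fdr.cell_size**2 / 1e6,
    })
    return cat_grid, topology, areas


# ---------------------------------------------------------------------------
# full scenarios
# ---------------------------------------------------------------------------

def _default_intents(rng: np.random.Generator, shape, streamlines) -> list[WetlandIntent]:
    """One wetland of each class plus an engineered Unclassified case,
    anchored on separate row bands with staggered columns so their
    flowpaths stay disjoint."""
    n_rows, n_cols = shape
    valley = n_rows // 2
    channel_cols = np.flatnonzero(streamlines.values[valley] == 1)
    if channel_cols.size == 0:
        raise GenerationError("no stream on the valley row; lower the threshold")
    c0 = int(channel_cols.min())
    jitter = int(rng.integers(0, 3))
    plan = [
        (ConnectivityClass.RIPARIAN, valley - 1, c0 + 3 + jitter),
        (ConnectivityClass.NRSHW, valley - 4, c0 + 10 + jitter),
        (ConnectivityClass.NRMID, valley - 6, c0 + 20 + jitter),
        (ConnectivityClass.NRDEEP, valley - 8, c0 + 30 + jitter),
        (ConnectivityClass.UNCLASSIFIED, valley - 10, c0 + 40 + jitter),
    ]
    intents = []
    for cls, row, col in plan:
        if not (0 <= row < n_rows and 0 <= col < n_cols - 6):
            raise GenerationError(
                f"default anchor for {cls.value} falls outside a {shape} grid"
            )
        intents.append(WetlandIntent(cls, anchor=(row, col), n_pixels=4))
    return intents


def build_scenario(spec: ScenarioSpec, verify: bool = True) -> ScenarioBundle:
    """Generate a complete input bundle and (optionally) self-verify it.

    With ``verify=True`` the real pipeline (delineation + classification)
    is run on the finished bundle and every engineered wetland's class is
    checked against its intent; a mismatch raises :class:`ScenarioError`.
    """
    n_rows, n_cols = spec.shape
    threshold = (
        spec.stream_threshold if spec.stream_threshold is not None else 4 * n_rows
    )
    dem = generate_terrain(
        spec.seed, spec.shape, spec.relief, spec.noise_amplitude, spec.cell_size
    )
    fdr, acc, streamlines = derive_hydrology(dem, threshold)

    landcover = dem.like(
        np.full(spec.shape, LAND_CODE, dtype=np.int32), layer_kind="landcover",
        nodata=0,
    )
    # give some stream cells open-water land cover so the buffered-streams
    # union draws on both sources
    stream_rc = np.argwhere(streamlines.values == 1)
    for row, col in stream_rc[::3]:
        landcover.values[row, col] = OPEN_WATER_CODE
    ksat = dem.like(np.full(spec.shape, 10.0), layer_kind="ksat", nodata=SOIL_NODATA)
    drainage = dem.like(
        np.full(spec.shape, 3, dtype=np.int32), layer_kind="drainage", nodata=-1
    )

    streams = build_buffered_streams(landcover, streamlines)
    rng = np.random.default_rng(spec.seed + 1)
    intents = spec.wetlands if spec.wetlands is not None else _default_intents(
        rng, spec.shape, streamlines
    )

    claimed: set[tuple[int, int]] = set()
    truth_rows = []
    for intent in intents:
        if intent.anchor is None:
            raise PlacementError("explicit anchors are required per intent")
        row = place_wetland(
            landcover, fdr, acc, streams, ksat, drainage,
            intent.anchor, intent.n_pixels, intent.intended_class, claimed,
        )
        truth_rows.append(row)

    catchments, topology, areas = generate_catchments(
        streamlines, fdr, spec.n_catchments
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["anchor_row", "anchor_col", "intended_class", "n_pixels"],
    )

    bundle = ScenarioBundle(
        spec=spec, dem=dem, landcover=landcover, fdr=fdr, accumulation=acc,
        streamlines=streamlines, catchments=catchments, ksat=ksat,
        drainage=drainage, truth=truth, topology=topology, catchment_areas=areas,
    )
    if verify:
        verify_bundle(bundle)
    return bundle


def truth_with_wet_ids(bundle: ScenarioBundle, units: list[WetlandUnit]) -> pd.DataFrame:
    """Attach the pipeline's WetIds to the truth table via anchor lookup."""
    labels = units_to_label_grid(units, bundle.landcover)
    truth = bundle.truth.copy()
    truth["wet_id"] = [
        int(labels.values[row, col])
        for row, col in zip(truth["anchor_row"], truth["anchor_col"])
    ]
    return truth


def verify_bundle(bundle: ScenarioBundle) -> pd.DataFrame:
    """Run the pipeline on the bundle and check classes against the truth."""
    units = delineate(bundle.landcover, bundle.catchments, bundle.accumulation)
    labels = units_to_label_grid(units, bundle.landcover)
    result = classify_all(
        units, bundle.fdr, bundle.stream_mask(), bundle.ksat, bundle.drainage,
        wet_labels=labels,
    )
    truth = truth_with_wet_ids(bundle, units)
    merged = truth.merge(result, on="wet_id", how="left")
    bad = merged[merged["intended_class"] != merged["connectivity_class"]]
    if not bad.empty:
        rows = bad[["wet_id", "intended_class", "connectivity_class"]]
        raise ScenarioError(
            f"pipeline disagrees with the truth table:\n{rows.to_string(index=False)}"
        )
    return merged
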