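"""End-to-end orchestration: delineate -> streams -> classify -> summarize.

A :class:`RunConfig` names the aligned input rasters and options;
:func:`run_pipeline` checks alignment up front, runs every stage, writes
the tabular artifacts (classified.csv, summaries.csv, stats.csv) and an
optional flowpath raster, and returns the in-memory results.  Per-wetland
failures degrade that wetland to Unclassified; stage-level failures abort
with the stage named.  Outputs are deterministic for a given config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import DEFAULT_KSAT_THRESHOLD, classify_all, trace_flowpath
from .delineation import delineate, units_to_label_grid
from .d8 import flow_accumulation
from .grid import RasterGrid, assert_aligned, read_raster, write_raster
from .streams import build_buffered_streams
from .summary import accumulate_watershed, local_percentages, summary_statistics

log = logging.getLogger("wetconnect")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs and options for a full classification run."""

    landcover: str
    streamlines: str
    catchments: str
    ksat: str
    drainage: str
    fdr: str | None = None
    accumulation: str | None = None
    dem: str | None = None  # fdr/accumulation derived from it when given
    topology: str | None = None  # from_id,to_id CSV for watershed accumulation
    catchment_areas: str | None = None  # catchment_id,area_km2 CSV
    out_dir: str = "."
    ksat_threshold: float = DEFAULT_KSAT_THRESHOLD
    connectivity: int = 8
    domain_area_km2: float | None = None  # default: full grid area
    write_paths_raster: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class PipelineResult:
    classified: pd.DataFrame
    summaries: pd.DataFrame
    stats: pd.DataFrame
    stage_counts: dict = field(default_factory=dict)


def _load_inputs(config: RunConfig) -> dict[str, RasterGrid]:
    grids = {
        "landcover": read_raster(config.landcover, "landcover"),
        "streamlines": read_raster(config.streamlines, "stream"),
        "catchments": read_raster(config.catchments, "catchment"),
        "ksat": read_raster(config.ksat, "ksat"),
        "drainage": read_raster(config.drainage, "drainage"),
    }
    if config.dem is not None:
        from .d8 import d8_from_dem

        dem = read_raster(config.dem, "dem")
        grids["fdr"] = d8_from_dem(dem)
        grids["accumulation"] = flow_accumulation(grids["fdr"])
    else:
        if config.fdr is None:
            raise ValueError("either 'dem' or 'fdr' must be configured")
        grids["fdr"] = read_raster(config.fdr, "flowdir")
        grids["accumulation"] = (
            read_raster(config.accumulation, "accumulation")
            if config.accumulation is not None
            else flow_accumulation(grids["fdr"])
        )
    return grids


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full classification chain and write its artifacts."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        grids = _load_inputs(config)
        assert_aligned(*grids.values())

        stage = "delineate"
        units = delineate(
            grids["landcover"], grids["catchments"], grids["accumulation"],
            connectivity=config.connectivity,
        )
        labels = units_to_label_grid(units, grids["landcover"])

        stage = "streams"
        streams = build_buffered_streams(grids["landcover"], grids["streamlines"])

        stage = "classify"
        classified = classify_all(
            units, grids["fdr"], streams, grids["ksat"], grids["drainage"],
            wet_labels=labels, threshold=config.ksat_threshold,
        )

        stage = "summarize"
        if config.catchment_areas is not None:
            areas = pd.read_csv(config.catchment_areas)
        else:
            vals = grids["catchments"].values
            ids, counts = np.unique(
                vals[vals != grids["catchments"].nodata], return_counts=True
            )
            areas = pd.DataFrame({
                "catchment_id": ids.astype(int),
                "area_km2": counts * grids["catchments"].cell_size**2 / 1e6,
            })
        summaries = local_percentages(classified, areas)
        if config.topology is not None:
            topology = pd.read_csv(config.topology)
            summaries = accumulate_watershed(summaries, topology)
        domain = (
            config.domain_area_km2
            if config.domain_area_km2 is not None
            else grids["landcover"].values.size
            * grids["landcover"].cell_size**2 / 1e6
        )
        stats = summary_statistics(classified, domain)

        stage = "write"
        classified.to_csv(out_dir / "classified.csv", index=False)
        summaries.to_csv(out_dir / "summaries.csv", index=False)
        stats.to_csv(out_dir / "stats.csv", index=False)
        write_raster(labels, out_dir / "wetland_ids.asc")
        if config.write_paths_raster:
            paths = np.zeros(grids["fdr"].shape, dtype=np.int8)
            for _, rec in classified.iterrows():
                unit = next(u for u in units if u.wet_id == rec["wet_id"])
                if rec["adjacent"] or unit.pour_point is None:
                    continue
                fp = trace_flowpath(unit.pour_point, grids["fdr"], streams)
                for row, col in fp.cells:
                    paths[row, col] = 1
            write_raster(
                grids["fdr"].like(paths, layer_kind="stream", nodata=0),
                out_dir / "flowpaths.asc",
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    counts = classified["connectivity_class"].value_counts().to_dict()
    log.info("wetconnect %s: %d wetland units; per-class counts: %s",
             __version__, len(classified), counts)
    return PipelineResult(classified, summaries, stats,
                          stage_counts={"units": len(classified), **counts})
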