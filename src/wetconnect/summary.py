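"""Per-catchment and per-watershed summaries of classified wetlands.

A *catchment* is the local area draining to one stream segment; its
*watershed* adds every upstream catchment.  Class extent is expressed as
percent of catchment (or watershed) area occupied by wetlands of each
connectivity class.  Watershed percentages are computed by summing areas
over the upstream tree before dividing — averaging percentages would not
be area-consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import ConnectivityClass

__all__ = [
    "CLASS_ORDER",
    "TopologyError",
    "local_percentages",
    "accumulate_watershed",
    "summary_statistics",
    "class_statistics",
    "dominant_class",
]

#: fixed class order, also the dominance tie precedence (decreasing connectivity)
CLASS_ORDER = [c.value for c in (
    ConnectivityClass.RIPARIAN,
    ConnectivityClass.NRSHW,
    ConnectivityClass.NRMID,
    ConnectivityClass.NRDEEP,
    ConnectivityClass.UNCLASSIFIED,
)]


class TopologyError(ValueError):
    """The from->to catchment topology contains a cycle."""


def _class_area_table(records: pd.DataFrame) -> pd.DataFrame:
    """Catchment x class wetland-area matrix (km^2) from the wetland table."""
    recs = records.dropna(subset=["catchment_id"])
    pivot = recs.pivot_table(
        index="catchment_id",
        columns="connectivity_class",
        values="area_km2",
        aggfunc="sum",
        fill_value=0.0,
    )
    for cls in CLASS_ORDER:
        if cls not in pivot.columns:
            pivot[cls] = 0.0
    return pivot[CLASS_ORDER]


def local_percentages(
    records: pd.DataFrame, catchment_areas: pd.DataFrame
) -> pd.DataFrame:
    """Percent of each catchment's area in each connectivity class.

    ``catchment_areas`` needs columns ``catchment_id`` and ``area_km2``.
    Every catchment referenced by a wetland record must appear there.
    Catchments with no wetlands get 0% everywhere and no dominant class.
    """
    areas = catchment_areas.set_index("catchment_id")["area_km2"]
    class_area = _class_area_table(records)
    missing = set(class_area.index) - set(areas.index)
    if missing:
        raise KeyError(f"catchments missing from the areas table: {sorted(missing)}")

    out = pd.DataFrame({"catchment_id": areas.index, "local_area_km2": areas.values})
    out = out.set_index("catchment_id")
    for cls in CLASS_ORDER:
        wet = class_area[cls].reindex(areas.index, fill_value=0.0)
        out[f"area_{cls}"] = wet
        out[f"pct_{cls}"] = 100.0 * wet / areas
    out["dominant_class"] = [
        dominant_class({cls: out.loc[c, f"area_{cls}"] for cls in CLASS_ORDER})
        for c in out.index
    ]
    return out.reset_index()


def accumulate_watershed(
    summaries: pd.DataFrame, topology: pd.DataFrame
) -> pd.DataFrame:
    """Fill watershed percentages by summing areas over upstream catchments.

    ``topology`` has columns ``from_id`` and ``to_id`` (downstream link of
    each catchment; catchments absent as ``from_id`` are outlets).  The
    topology must be acyclic.  For each catchment, watershed land area and
    per-class wetland area are the sums over the catchment and everything
    upstream of it; percentages are the ratio of those sums.
    """
    import networkx as nx

    graph = nx.DiGraph()
    graph.add_nodes_from(summaries["catchment_id"])
    for _, row in topology.iterrows():
        if pd.isna(row["to_id"]):
            continue
        graph.add_edge(row["from_id"], row["to_id"])
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise TopologyError(f"catchment topology contains a cycle: {cycle}")

    out = summaries.set_index("catchment_id").copy()
    ws_land = out["local_area_km2"].to_dict()
    ws_class = {
        cls: out[f"area_{cls}"].to_dict() for cls in CLASS_ORDER
    }
    for node in nx.topological_sort(graph):
        for succ in graph.successors(node):
            ws_land[succ] = ws_land.get(succ, 0.0) + ws_land.get(node, 0.0)
            for cls in CLASS_ORDER:
                ws_class[cls][succ] = (
                    ws_class[cls].get(succ, 0.0) + ws_class[cls].get(node, 0.0)
                )

    out["watershed_area_km2"] = [ws_land[c] for c in out.index]
    for cls in CLASS_ORDER:
        area = np.array([ws_class[cls][c] for c in out.index])
        out[f"ws_area_{cls}"] = area
        out[f"ws_pct_{cls}"] = 100.0 * area / out["watershed_area_km2"]
    return out.reset_index()


def class_statistics(
    counts: dict[str, int], areas_km2: dict[str, float], domain_area_km2: float
) -> pd.DataFrame:
    """Per-class count / total area / mean area / percent-of-domain table.

    The returned frame has one row per connectivity class plus a ``Total``
    row whose count and area are the column sums.  Mean area is NaN for
    empty classes.
    """
    if domain_area_km2 <= 0:
        raise ValueError("domain area must be positive")
    rows = []
    for cls in CLASS_ORDER:
        n = int(counts.get(cls, 0))
        area = float(areas_km2.get(cls, 0.0))
        rows.append({
            "class": cls,
            "n_wetlands": n,
            "total_area_km2": area,
            "mean_area_km2": area / n if n else np.nan,
            "pct_of_domain": 100.0 * area / domain_area_km2,
        })
    n_total = sum(r["n_wetlands"] for r in rows)
    area_total = sum(r["total_area_km2"] for r in rows)
    rows.append({
        "class": "Total",
        "n_wetlands": n_total,
        "total_area_km2": area_total,
        "mean_area_km2": area_total / n_total if n_total else np.nan,
        "pct_of_domain": 100.0 * area_total / domain_area_km2,
    })
    return pd.DataFrame(rows)


def summary_statistics(records: pd.DataFrame, domain_area_km2: float) -> pd.DataFrame:
    """Class statistics computed from a classified wetland table."""
    grouped = records.groupby("connectivity_class")
    counts = grouped.size().to_dict()
    areas = grouped["area_km2"].sum().to_dict()
    return class_statistics(counts, areas, domain_area_km2)


def dominant_class(class_areas: dict[str, float]) -> str | None:
    """Class with the greatest wetland area; ties break by decreasing
    connectivity (Riparian > NRShw > NRMid > NRDeep > Unclassified);
    ``None`` when there is no wetland area at all."""
    best: str | None = None
    best_area = 0.0
    for cls in CLASS_ORDER:  # precedence order: earlier wins ties
        area = class_areas.get(cls, 0.0)
        if area > best_area:
            best, best_area = cls, area
    return best
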