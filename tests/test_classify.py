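import itertools
import math

import numpy as np
import pandas as pd
import pytest

import oracles
from wetconnect.classify import (
    ConnectivityClass as C,
    DEFAULT_KSAT_THRESHOLD,
    DrainageCodeError,
    Flowpath,
    FlowpathSoil,
    Terminal,
    classify_all,
    classify_wetland,
    path_majority_drainage,
    path_min_ksat,
    trace_flowpath,
)
from wetconnect.delineation import delineate, units_to_label_grid
from wetconnect.d8 import flow_accumulation
from wetconnect.grid import RasterGrid
from wetconnect.streams import build_buffered_streams
from wetconnect.synthetic import build_scenario, ScenarioSpec, truth_with_wet_ids


def grid(values, **kw):
    return RasterGrid(np.asarray(values), **kw)


def stream_mask(stream_cells, shape):
    lc = grid(np.full(shape, 41), nodata=0)
    lines = grid(np.zeros(shape, dtype=int), nodata=-1)
    for cell in stream_cells:
        lines.values[cell] = 1
    return build_buffered_streams(lc, lines)


class TestTraceFlowpath:
    def test_straight_walk_stops_before_the_stream(self):
        fdr = grid(np.full((1, 5), 1), nodata=0)  # all east
        streams = stream_mask([(0, 4)], (1, 5))
        path = trace_flowpath((0, 1), fdr, streams)
        assert path.terminal is Terminal.REACHED_STREAM
        assert path.cells == [(0, 1), (0, 2), (0, 3)]  # land cells only
        assert path.length_m == pytest.approx(60.0)

    def test_pour_point_next_to_stream_gives_length_one_path(self):
        fdr = grid(np.full((1, 3), 1), nodata=0)
        streams = stream_mask([(0, 2)], (1, 3))
        path = trace_flowpath((0, 1), fdr, streams)
        assert path.ok and path.cells == [(0, 1)] and path.length_m == 0.0

    def test_two_cycle_is_flagged(self):
        fdr = grid([[1, 16, 1]], nodata=0)
        path = trace_flowpath((0, 0), fdr, stream_mask([], (1, 3)))
        assert path.terminal is Terminal.LOOP_DETECTED

    def test_grid_exit_and_nodata_terminals(self):
        fdr = grid([[1, 1]], nodata=0)
        assert (
            trace_flowpath((0, 0), fdr, stream_mask([], (1, 2))).terminal
            is Terminal.EXITED_GRID
        )
        fdr2 = grid([[1, 0]], nodata=0)
        assert (
            trace_flowpath((0, 0), fdr2, stream_mask([], (1, 2))).terminal
            is Terminal.HIT_NODATA
        )

    def test_step_budget_exhaustion(self):
        fdr = grid(np.full((1, 10), 1), nodata=0)
        path = trace_flowpath((0, 0), fdr, stream_mask([], (1, 10)), max_steps=3)
        assert path.terminal is Terminal.MAX_STEPS and len(path.cells) == 4

    def test_diagonal_steps_have_sqrt2_length(self):
        fdr = grid([[2, 0], [0, 2]], nodata=0)  # SE
        path = trace_flowpath((0, 0), fdr, stream_mask([], (2, 2)))
        assert path.step_lengths == [pytest.approx(30 * math.sqrt(2))]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_step_by_step_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fdr_vals = oracles.random_acyclic_fdr(rng, (10, 10))
        stream = rng.random((10, 10)) < 0.1
        fdr = grid(fdr_vals, nodata=0)
        streams = stream_mask(map(tuple, np.argwhere(stream)), (10, 10))
        for _ in range(5):
            start = tuple(rng.integers(0, 10, size=2))
            got = trace_flowpath(start, fdr, streams)
            cells, terminal = oracles.walk_to_stream(fdr_vals, stream, start, 100)
            assert got.cells == cells
            assert got.terminal.value == terminal

    def test_paths_never_contain_stream_cells(self, scenario):
        streams = scenario.stream_mask()
        units = delineate(
            scenario.landcover, scenario.catchments, scenario.accumulation
        )
        for unit in units:
            path = trace_flowpath(unit.pour_point, scenario.fdr, streams)
            assert not any(streams.is_stream(*cell) for cell in path.cells[1:])


class TestSoilAggregation:
    def path(self, cells, steps=None):
        steps = steps if steps is not None else [30.0] * (len(cells) - 1)
        return Flowpath(list(cells), Terminal.REACHED_STREAM, steps)

    def test_minimum_ksat_is_limiting(self):
        ksat = grid([[10.0, 6.0, 3.0]], nodata=-9999.0)
        assert path_min_ksat(self.path([(0, 0), (0, 1), (0, 2)]), ksat) == 3.0

    def test_single_cell_path(self):
        ksat = grid([[7.2]], nodata=-9999.0)
        assert path_min_ksat(self.path([(0, 0)]), ksat) == 7.2

    def test_all_nodata_ksat_is_undefined(self):
        ksat = grid([[-9999.0, -9999.0]], nodata=-9999.0)
        assert path_min_ksat(self.path([(0, 0), (0, 1)]), ksat) is None

    def test_nodata_cells_skipped_not_poisoning(self):
        ksat = grid([[10.0, -9999.0, 6.0]], nodata=-9999.0)
        assert path_min_ksat(self.path([(0, 0), (0, 1), (0, 2)]), ksat) == 6.0

    def test_majority_by_count_on_cardinal_path(self):
        drainage = grid([[6, 6, 3]], nodata=-1)
        assert (
            path_majority_drainage(self.path([(0, 0), (0, 1), (0, 2)]), drainage)
            == "poorly_drained"
        )

    def test_diagonal_step_outweighs_cardinal_pour_cell(self):
        # pour cell poorly drained (weight 30), diagonal-step cell well
        # drained (weight 30*sqrt(2)): well drained wins on length
        drainage = grid([[6, -1], [-1, 3]], nodata=-1)
        path = self.path([(0, 0), (1, 1)], steps=[30 * math.sqrt(2)])
        assert path_majority_drainage(path, drainage) == "well_drained"

    def test_exact_tie_goes_to_poorly_drained(self):
        drainage = grid([[6, 3]], nodata=-1)
        assert (
            path_majority_drainage(self.path([(0, 0), (0, 1)]), drainage)
            == "poorly_drained"
        )

    def test_unknown_drainage_code_is_a_data_error(self):
        drainage = grid([[9]], nodata=-1)
        with pytest.raises(DrainageCodeError, match="9"):
            path_majority_drainage(self.path([(0, 0)]), drainage)

    def test_all_seven_nrcs_codes_map_to_a_group(self):
        for code in range(1, 8):
            drainage = grid([[code]], nodata=-1)
            group = path_majority_drainage(self.path([(0, 0)]), drainage)
            assert group == ("well_drained" if code <= 4 else "poorly_drained")


class TestClassifyWetland:
    def soil(self, ksat, drain):
        return FlowpathSoil(ksat, drain, 1, 1)

    def test_adjacency_decides_first_ignoring_soils(self):
        assert classify_wetland(True, self.soil(1.0, "poorly_drained")) is C.RIPARIAN
        assert classify_wetland(True, None, path_ok=False) is C.RIPARIAN

    def test_impermeable_path_is_nrdeep_regardless_of_drainage(self):
        for drain in ("poorly_drained", "well_drained", None):
            assert classify_wetland(False, self.soil(3.0, drain)) is C.NRDEEP

    def test_permeable_path_splits_on_drainage(self):
        assert classify_wetland(False, self.soil(10.0, "poorly_drained")) is C.NRSHW
        assert classify_wetland(False, self.soil(10.0, "well_drained")) is C.NRMID

    def test_threshold_equality_counts_as_permeable(self):
        soil = self.soil(DEFAULT_KSAT_THRESHOLD, "well_drained")
        assert classify_wetland(False, soil) is C.NRMID

    def test_exhaustive_truth_table(self):
        """Every combination of the decision inputs maps to the documented
        class; no combination is unmapped."""
        thr = DEFAULT_KSAT_THRESHOLD
        ksat_levels = {"below": thr - 1, "equal": thr, "above": thr + 1,
                       "undefined": None}
        drain_levels = {"poor": "poorly_drained", "well": "well_drained",
                        "undefined": None}

        def expected(adjacent, ksat_key, drain_key, path_ok):
            if adjacent:
                return C.RIPARIAN
            if not path_ok or ksat_key == "undefined":
                return C.UNCLASSIFIED
            if ksat_key == "below":
                return C.NRDEEP
            return {"poor": C.NRSHW, "well": C.NRMID,
                    "undefined": C.UNCLASSIFIED}[drain_key]

        combos = itertools.product(
            (True, False), ksat_levels, drain_levels, (True, False)
        )
        for adjacent, kkey, dkey, path_ok in combos:
            soil = self.soil(ksat_levels[kkey], drain_levels[dkey])
            got = classify_wetland(adjacent, soil, thr, path_ok)
            assert got is expected(adjacent, kkey, dkey, path_ok), (
                adjacent, kkey, dkey, path_ok
            )

    def test_threshold_monotonicity_only_moves_toward_nrdeep(self):
        soils = [self.soil(k, d) for k in (1.0, 5.0, 5.08, 8.0, 20.0)
                 for d in ("poorly_drained", "well_drained")]
        rank = {C.NRSHW: 0, C.NRMID: 0, C.NRDEEP: 1}
        for soil in soils:
            previous = None
            for thr in (0.5, 2.0, 5.08, 10.0, 50.0):
                cls = classify_wetland(False, soil, thr)
                if previous is not None:
                    assert rank[cls] >= rank[previous]
                previous = cls


class TestClassifyAll:
    def test_synthetic_scenario_reproduces_ground_truth(self, scenario):
        units = delineate(
            scenario.landcover, scenario.catchments, scenario.accumulation
        )
        labels = units_to_label_grid(units, scenario.landcover)
        table = classify_all(
            units, scenario.fdr, scenario.stream_mask(), scenario.ksat,
            scenario.drainage, wet_labels=labels,
        )
        truth = truth_with_wet_ids(scenario, units)
        merged = truth.merge(table, on="wet_id")
        assert (merged["intended_class"] == merged["connectivity_class"]).all()
        assert set(merged["intended_class"]) == {c.value for c in C}

    def test_zero_wetlands_gives_empty_table(self):
        fdr = grid(np.full((3, 3), 1), nodata=0)
        table = classify_all(
            [], fdr, stream_mask([], (3, 3)),
            grid(np.full((3, 3), 10.0), nodata=-9999.0),
            grid(np.full((3, 3), 3), nodata=-1),
        )
        assert table.empty and "connectivity_class" in table.columns

    def test_path_exiting_grid_is_unclassified(self):
        lc = grid(np.full((3, 3), 41), nodata=0)
        lc.values[1, 0] = 95
        fdr = grid(np.full((3, 3), 1), nodata=0)  # east, no stream: exits
        cats = grid(np.ones((3, 3), dtype=int), nodata=-1)
        units = delineate(lc, cats, flow_accumulation(fdr))
        table = classify_all(
            units, fdr, stream_mask([], (3, 3)),
            grid(np.full((3, 3), 10.0), nodata=-9999.0),
            grid(np.full((3, 3), 3), nodata=-1),
        )
        assert table.loc[0, "connectivity_class"] == "Unclassified"
        assert table.loc[0, "terminal"] == "exited_grid"

    def test_riparian_invariant_to_soil_grids(self, scenario):
        units = delineate(
            scenario.landcover, scenario.catchments, scenario.accumulation
        )
        streams = scenario.stream_mask()
        rng = np.random.default_rng(0)
        base = classify_all(units, scenario.fdr, streams, scenario.ksat,
                            scenario.drainage)
        shuffled_ksat = scenario.ksat.like(
            rng.permutation(scenario.ksat.values.ravel()).reshape(scenario.ksat.shape)
        )
        shuffled_drain = scenario.drainage.like(
            rng.permutation(scenario.drainage.values.ravel()).reshape(
                scenario.drainage.shape
            )
        )
        alt = classify_all(units, scenario.fdr, streams, shuffled_ksat, shuffled_drain)
        rip = base["connectivity_class"] == "Riparian"
        assert rip.any()
        assert (alt.loc[rip, "connectivity_class"] == "Riparian").all()

    def test_downstream_wetlands_recorded_in_order(self):
        # wetland A at (0,0) drains east through wetland B at (0,2)
        lc = grid([[95, 41, 95, 41, 41]], nodata=0)
        fdr = grid(np.full((1, 5), 1), nodata=0)
        cats = grid(np.ones((1, 5), dtype=int), nodata=-1)
        streams = stream_mask([(0, 4)], (1, 5))
        units = delineate(lc, cats, flow_accumulation(fdr))
        labels = units_to_label_grid(units, lc)
        table = classify_all(
            units, fdr, streams,
            grid(np.full((1, 5), 10.0), nodata=-9999.0),
            grid(np.full((1, 5), 3), nodata=-1),
            wet_labels=labels,
        )
        a = table[table["wet_id"] == 1].iloc[0]
        assert a["downstream_wet_ids"] == "2"
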