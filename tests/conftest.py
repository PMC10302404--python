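from pathlib import Path

import numpy as np
import pytest

from wetconnect.grid import RasterGrid, read_raster
from wetconnect.synthetic import ScenarioSpec, build_scenario

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def handmade():
    """The hand-written 12x12 fixture family as loaded grids + truth."""
    import pandas as pd

    p = FIXTURES / "handmade"
    return {
        "landcover": read_raster(p / "landcover.asc", "landcover"),
        "fdr": read_raster(p / "fdr.asc", "flowdir"),
        "streamlines": read_raster(p / "streamlines.asc", "stream"),
        "catchments": read_raster(p / "catchments.asc", "catchment"),
        "ksat": read_raster(p / "ksat.asc", "ksat"),
        "drainage": read_raster(p / "drainage.asc", "drainage"),
        "truth": pd.read_csv(p / "truth.csv"),
        "dir": p,
    }


@pytest.fixture(scope="session")
def scenario():
    """One verified default synthetic scenario (all classes present)."""
    return build_scenario(ScenarioSpec(seed=7))


def make_grid(values, **kwargs) -> RasterGrid:
    return RasterGrid(np.asarray(values), **kwargs)
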