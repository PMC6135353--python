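import numpy as np
import pytest

from kernelscape import landcover as lc
from kernelscape.experts import aggregate_ratings
from kernelscape.resistance import ResistanceGrid, SourcePointSet, build_resistance
from kernelscape.raster import RasterGrid


@pytest.fixture(scope="session")
def small_scenario():
    """A 60x60 instance of the packaged synthetic scenario."""
    return lc.make_demo_scenario(7, shape=(60, 60))


@pytest.fixture(scope="session")
def small_suitability(small_scenario):
    return aggregate_ratings(small_scenario.panel)


@pytest.fixture(scope="session")
def small_resistance(small_scenario, small_suitability):
    return build_resistance(small_scenario.grids[0], small_suitability)


def uniform_resistance(rows, cols, value=1.0, cell_size=1000.0, label="u"):
    return ResistanceGrid(
        RasterGrid(np.full((rows, cols), float(value)), cell_size), label
    )


def strip_sources(cols, rows_index=0):
    pts = np.array([[rows_index, c] for c in cols])
    return SourcePointSet(pts, threshold=0.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
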