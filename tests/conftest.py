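import numpy as np
import pytest

from mcfmap.raster import RasterGrid
from mcfmap.synthetic import LandscapeConfig, Massif, McfRule, generate_world


def small_landscape_config(seed: int = 7) -> LandscapeConfig:
    """A 160x160 (4.8 km) world that keeps every downstream stage fast.

    Relief is scaled to the smaller domain; a cleared lowland corner
    guarantees both forest classes exist.
    """
    return LandscapeConfig(
        grid_rows=160,
        grid_cols=160,
        n_scenes=80,
        n_plots=200,
        n_forest_points=120,
        seed=seed,
        relief=[
            Massif((2400.0, 2000.0), 2800.0, 900.0),
            Massif((1600.0, 3600.0), 2200.0, 700.0),
            Massif((4000.0, 1200.0), 1300.0, 400.0),
        ],
        mcf_rule=McfRule(cleared_rects=[(0.0, 1200.0, 0.0, 1200.0)]),
    )


@pytest.fixture(scope="session")
def small_config():
    return small_landscape_config()


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def grid(data, cell=1.0, origin=None, nodata=None) -> RasterGrid:
    data = np.asarray(data)
    if origin is None:
        origin = (0.0, data.shape[0] * cell)
    return RasterGrid(data=data, cell_size=cell, origin=origin, nodata=nodata)
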