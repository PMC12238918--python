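import numpy as np
import pytest

from oligotrend import synth
from oligotrend.raster import GridRaster


@pytest.fixture(scope="session")
def default_cfg() -> synth.SynthConfig:
    return synth.SynthConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_cfg):
    """One full synthetic bundle shared across the session (read-only)."""
    return synth.generate_bundle(default_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_tilted_plane(nrows=10, ncols=12, slope=1.0, cell_size=100.0,
                      axis="col") -> GridRaster:
    """Plane rising along one index axis; already drained."""
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    z = slope * (cols if axis == "col" else rows).astype(float)
    return GridRaster(values=z, cell_size=cell_size)


def random_dem(rng, nrows=20, ncols=20, cell_size=100.0) -> GridRaster:
    """Rough random terrain with plenty of pits."""
    z = rng.uniform(0, 10, size=(nrows, ncols))
    return GridRaster(values=z, cell_size=cell_size)
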