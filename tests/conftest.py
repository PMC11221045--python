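import numpy as np
import pandas as pd
import pytest

from benthotrack.raster import NODATA, BenthoscapeRaster
from benthotrack.simulate import SimulationConfig, T0


@pytest.fixture
def small_raster():
    """2x2 raster, 10 m cells, origin (0,0): [[0,1],[2,3]] south-up."""
    return BenthoscapeRaster(
        origin_x=0.0, origin_y=0.0, cell_size=10.0,
        values=np.array([[0, 1], [2, 3]]),
    )


@pytest.fixture
def uniform_raster():
    return BenthoscapeRaster(
        origin_x=0.0, origin_y=0.0, cell_size=10.0,
        values=np.full((20, 20), 4),
    )


@pytest.fixture
def default_config():
    return SimulationConfig()


def make_fixes(t_seconds, tag_id="BL 001", x=None, y=None, hpe=1.0, release=None):
    """Fix table at the given offsets (s) from the epoch."""
    t_seconds = np.asarray(t_seconds, dtype=float)
    n = t_seconds.size
    return pd.DataFrame(
        {
            "tag_id": tag_id,
            "is_sync": False,
            "t": T0 + pd.to_timedelta(t_seconds, unit="s"),
            "x_m": np.zeros(n) if x is None else np.asarray(x, dtype=float),
            "y_m": np.zeros(n) if y is None else np.asarray(y, dtype=float),
            "hpe": np.broadcast_to(np.asarray(hpe, dtype=float), (n,)).copy(),
            "hpem": np.nan,
            "release_t": T0 if release is None else release,
            "deployment_id": "D1",
        }
    )
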