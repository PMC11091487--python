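import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from wolfscr.grid import build_grid
from wolfscr.occupancy import OccupancyData
from wolfscr.scr import SCRData


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid5():
    return build_grid(5, 5, seed=7)


def make_occ_data(events, G, camera_events=None):
    """OccupancyData from an event matrix; unit effort where observed."""
    events = np.asarray(events, dtype=int)
    eff = np.where(events >= 0, 1.0, 0.0)
    kwargs = {}
    if camera_events is not None:
        camera_events = np.asarray(camera_events, dtype=int)
        kwargs["camera_events"] = camera_events
        kwargs["effort_camera"] = np.where(camera_events >= 0, 1.0, 0.0)
    return OccupancyData(
        transect_events=events, effort_transect=eff, G=np.asarray(G, dtype=int),
        **kwargs,
    )


def make_detectors(grid, cells, area_id=0):
    rows = [
        {
            "detector_id": i,
            "cell_id": int(c),
            "x_km": float(grid.x[c]),
            "y_km": float(grid.y[c]),
            "area_id": area_id,
        }
        for i, c in enumerate(cells)
    ]
    return pd.DataFrame(rows)


def make_scr_data(grid, det_cells, y, sex=None):
    return SCRData(y=np.asarray(y, dtype=int),
                   detectors=make_detectors(grid, det_cells), sex=sex)
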