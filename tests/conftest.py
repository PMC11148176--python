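import numpy as np
import pytest

from cealab.gaze_core import GazeTrace, ScreenGeometry, deg_to_px
from cealab import config


@pytest.fixture(scope="session")
def geometry() -> ScreenGeometry:
    return ScreenGeometry()


def trace_from_deg(x_deg, y_deg, geometry=None, hz=config.GAZE_HZ,
                   valid=None, distance=None, t=None) -> GazeTrace:
    """Build a GazeTrace from degree coordinates on a uniform clock."""
    geometry = geometry or ScreenGeometry()
    x_deg = np.asarray(x_deg, dtype=float)
    y_deg = np.asarray(y_deg, dtype=float)
    n = len(x_deg)
    if t is None:
        t = np.arange(n) / hz
    if distance is None:
        distance = np.full(n, geometry.nominal_distance_mm)
    else:
        distance = np.broadcast_to(np.asarray(distance, float), (n,)).copy()
    x_px, y_px = deg_to_px(x_deg, y_deg, geometry, distance)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return GazeTrace(t=t, x_px=x_px, y_px=y_px, valid=np.asarray(valid, bool),
                     distance_mm=distance, geometry=geometry, hz=hz)
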