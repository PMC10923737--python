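import datetime as dt

import numpy as np
import pytest

from vhicast.core_io import RasterCube, StepKind, TimeAxis, Variable
from vhicast.preprocessing import build_calendar


def make_cube(values, variable=Variable.NDVI, mask=None, start=dt.date(2012, 1, 1),
              step_kind=StepKind.daily, composite=False):
    """Build a cube with a daily or 8-day composite time axis starting at `start`."""
    values = np.asarray(values, dtype=np.float32)
    T = values.shape[0]
    if composite:
        cal = build_calendar(start, start + dt.timedelta(days=8 * T + 30))
        ts = cal.starts()[:T]
        axis = TimeAxis(ts, StepKind.composite_8day)
    else:
        axis = TimeAxis(
            tuple(start + dt.timedelta(days=i) for i in range(T)), step_kind
        )
    return RasterCube(variable, values, mask, axis)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube_factory():
    return make_cube
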