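import numpy as np
import pytest

from ticcad import DceSeries, TimeCurve

TIMES_9 = 80.0 * np.arange(9)


def make_series(frames, times=None, case_id="test"):
    """Stack a list of H×W frames into a DceSeries."""
    data = np.stack([np.asarray(f, dtype=float) for f in frames])
    if times is None:
        times = 80.0 * np.arange(len(frames))
    return DceSeries(data=data, times=times, case_id=case_id)


def make_curve(values):
    values = np.asarray(values, dtype=float)
    return TimeCurve(values=values, times=80.0 * np.arange(len(values)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
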