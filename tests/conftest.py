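import numpy as np
import pytest

from vestigait.dva import build_chart
from vestigait.io import UniformSeries, YawSeries


@pytest.fixture(scope="session")
def chart():
    return build_chart()


@pytest.fixture
def make_uniform():
    """UniformSeries from a callable f(t) on [0, duration] at a given rate."""

    def _make(f, duration=5.0, rate=100.0, t0=0.0):
        t = t0 + np.arange(int(round(duration * rate)) + 1) / rate
        return UniformSeries(rate=rate, t0=t0, values=np.asarray(f(t), dtype=float))

    return _make


@pytest.fixture
def make_yaw():
    """YawSeries from a callable f(t) on [0, duration] at a given rate."""

    def _make(f, duration=5.0, rate=100.0, segment="head"):
        t = np.arange(int(round(duration * rate)) + 1) / rate
        return YawSeries(rate=rate, yaw_deg=np.asarray(f(t), dtype=float), segment=segment)

    return _make
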