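import numpy as np
import pytest

from steerstress.canbus_io import SteeringTrace
from steerstress.segmentation import SegmentationParams
from steerstress.synthetic_driving import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ramp_trace(points, rate=100.0, **kw) -> SteeringTrace:
    """Piecewise-linear trace through the given angle way-points.

    Consecutive way-points are connected by `rate`-Hz linear ramps of one
    second each, so valleys/peaks land exactly on the way-points.
    """
    segs = [np.linspace(a, b, int(rate), endpoint=False) for a, b in zip(points, points[1:])]
    angle = np.concatenate(segs + [[points[-1]]])
    return SteeringTrace(time=np.arange(angle.size) / rate, angle=angle, **kw)


@pytest.fixture
def default_params():
    return SegmentationParams()


@pytest.fixture
def noiseless_params():
    return SimParams(noise_sd=0.0, quantization=0.0)
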