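import numpy as np
import pytest

from afgkit.contour import PitchContour
from afgkit.stimgen import StimulusConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cfg():
    return StimulusConfig()


@pytest.fixture
def flat_contour():
    """1 s of constant 131 Hz at 100 frames/s."""
    return PitchContour(np.full(100, 131.0))


def make_contour(values, frame_rate=100.0):
    return PitchContour(np.asarray(values, dtype=float), frame_rate=frame_rate)
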