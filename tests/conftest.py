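import numpy as np
import pytest

from modspec import TimeSeries
from modspec import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def white_noise(rng):
    return TimeSeries(rng.standard_normal(8000), 1000.0, "noise")


@pytest.fixture
def clean_ecg_60():
    x, gt = synth.synth_ecg(hr_bpm=60.0, duration_s=60.0, fs=256.0, seed=7)
    return x, gt


@pytest.fixture
def am_tone():
    """AM tone: 100 Hz carrier, 5 Hz modulation, depth 0.5, 10 s at 1 kHz."""
    return synth.synth_am(100.0, 5.0, 0.5, 1000.0, 10.0)
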