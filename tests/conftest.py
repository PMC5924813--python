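import numpy as np
import pytest

from ansmap.beat_spectral import BeatSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240401)


@pytest.fixture
def single_sine_tachogram(rng):
    """300 beats, mean 1000 ms, one 0.10 cycles/beat sinusoid (amp 30 ms) + noise."""
    n = np.arange(300)
    x = 1000 + 30 * np.sin(2 * np.pi * 0.10 * n) + rng.normal(0, 5, 300)
    return BeatSeries(x, kind="RR")


@pytest.fixture
def two_sine_tachogram(rng):
    n = np.arange(300)
    x = (1000 + 30 * np.sin(2 * np.pi * 0.10 * n)
         + 25 * np.sin(2 * np.pi * 0.25 * n + 1.0) + rng.normal(0, 5, 300))
    return BeatSeries(x, kind="RR")
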