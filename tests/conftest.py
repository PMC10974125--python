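import numpy as np
import pytest


@pytest.fixture
def rate() -> float:
    return 1000.0


@pytest.fixture
def two_tone(rate):
    """2 Hz + 30 Hz unit tones, 4 s: the canonical separable fixture."""
    t = np.arange(int(4 * rate)) / rate
    low = np.sin(2 * np.pi * 2 * t)
    high = np.sin(2 * np.pi * 30 * t)
    return low + high, low, high


@pytest.fixture
def tone_30hz(rate):
    t = np.arange(int(4 * rate)) / rate
    return np.sin(2 * np.pi * 30 * t)
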