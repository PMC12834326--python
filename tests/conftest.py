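import numpy as np
import pytest

from dcemu.core import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_series(values, fs=1000.0, **kw):
    return TimeSeries(np.asarray(values, dtype=float), fs_hz=fs, **kw)


@pytest.fixture
def sine_series():
    """Factory for sine TimeSeries: (freq_hz, amp, duration_s, fs)."""
    def _make(freq_hz, amp=1.0, duration_s=10.0, fs=1000.0):
        t = np.arange(int(duration_s * fs)) / fs
        return make_series(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs)
    return _make
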