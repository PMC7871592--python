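import numpy as np
import pytest

from connkit import DEFAULT_BANDS, MultiChannelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def theta_band():
    return DEFAULT_BANDS["theta"]


@pytest.fixture
def sine_pair():
    """60 s, 200 Hz: identical 8 Hz sinusoids with light independent noise."""
    rate = 200.0
    t = np.arange(int(60 * rate)) / rate
    g = np.random.default_rng(7)
    x = np.cos(2 * np.pi * 8 * t) + 0.1 * g.standard_normal(t.size)
    y = np.cos(2 * np.pi * 8 * t) + 0.1 * g.standard_normal(t.size)
    return MultiChannelRecording(data=np.vstack([x, y]), rate_hz=rate, labels=["A", "B"])


@pytest.fixture
def fm_theta():
    """Theta LFP with cycle-to-cycle period jitter (needed for offset analyses)."""
    rate = 1000.0
    g = np.random.default_rng(11)
    periods = 1.0 / g.uniform(5.5, 11.5, size=1600)  # ~200 s of cycles
    trough_times = np.concatenate([[0.0], np.cumsum(periods)])
    n = int(trough_times[-1] * rate)
    t = np.arange(n) / rate
    cyc = np.interp(t, trough_times, np.arange(trough_times.size, dtype=float))
    lfp = -np.cos(2 * np.pi * cyc) + 0.05 * g.standard_normal(n)
    return lfp, rate
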