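import numpy as np
import pytest

from myotrain import Channel, PressureTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(values, fs=50.0, t0=0.0, channel=Channel.TONGUE):
    return PressureTrace(channel, np.asarray(values, dtype=float), fs=fs, t0=t0)


@pytest.fixture
def constant_trace():
    def _make(level, duration_s=10.0, fs=50.0, channel=Channel.TONGUE):
        n = round(duration_s * fs)
        return make_trace(np.full(n, level), fs=fs, channel=channel)

    return _make
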