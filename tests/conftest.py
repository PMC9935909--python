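import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_bank():
    """The 20-filter Mel bank on the standard 11.025 kHz analysis grid."""
    from melbreath.melscale import build_filterbank

    fs = 11025.0
    freqs = np.linspace(0.0, fs / 2.0, 513)
    return build_filterbank(20, 0.0, fs / 2.0, freqs)


def tcw_oracle(y: np.ndarray, fs: float, delta_s: float) -> np.ndarray:
    """Direct per-window evaluation of the sliding-variance waveform."""
    d = int(round(delta_s * fs))
    n = len(y)
    dt = 1.0 / fs
    out = np.empty(n)
    for t in range(n):
        w = y[max(0, t - d) : min(n - 1, t + d) + 1]
        wdur = len(w) * dt
        ybar = w.mean()
        out[t] = np.sum(w * w) * dt - wdur * ybar * ybar
    return out


def cmw_oracle(c: np.ndarray, fs: float, l_s: float) -> np.ndarray:
    """Direct per-window evaluation of the quadratic moment waveform."""
    L = int(round(l_s * fs))
    n = len(c)
    dt = 1.0 / fs
    out = np.empty(n)
    for t in range(n):
        a, b = max(0, t - L), min(n - 1, t + L)
        k = np.arange(a, b + 1) - t
        out[t] = np.sum((k * dt) ** 2 * c[a : b + 1]) * dt
    return out
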