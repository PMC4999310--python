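import numpy as np
import pytest

from synquant.types import Condition, QuantalParameters

# four-condition release-probability grid used throughout: human-like
# connection with N = 20 sites of q = 40 fC across a [Ca2+]o ladder
CONDITIONS = [
    Condition("ca0.5", 0.5, 0.10),
    Condition("ca1.5", 1.5, 0.33),
    Condition("ca2.0", 2.0, 0.50),
    Condition("ca4.0", 4.0, 0.80),
]


@pytest.fixture
def conditions():
    return list(CONDITIONS)


@pytest.fixture
def human_like_params():
    return QuantalParameters(n_sites=20, q_fc=40.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def alpha_waveform_oracle(tau_ms: float, grid_khz: float = 1000.0):
    """Dense-grid (1 MHz) evaluation of the normalized alpha waveform.

    Returns (rise_10_90_ms, decay_37_ms) measured by brute-force level
    crossings with linear interpolation — independent of the detection
    code path.
    """
    t = np.arange(0.0, 40.0 * tau_ms, 1.0 / grid_khz)
    f = (t / tau_ms) * np.exp(1.0 - t / tau_ms)
    ip = int(np.argmax(f))
    peak = f[ip]

    def rising_cross(level):
        j = int(np.flatnonzero(f[: ip + 1] >= level)[0])
        return float(np.interp(level, [f[j - 1], f[j]], [t[j - 1], t[j]]))

    t10 = rising_cross(0.1 * peak)
    t90 = rising_cross(0.9 * peak)
    j = ip + int(np.flatnonzero(f[ip:] <= 0.37 * peak)[0])
    t37 = float(np.interp(-0.37 * peak, [-f[j - 1], -f[j]], [t[j - 1], t[j]]))
    return t90 - t10, t37 - t[ip]
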