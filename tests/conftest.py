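import numpy as np
import pytest

from rfdkit.model import ForceTrace
from rfdkit.synthetic import LogisticProfile, simulate_trace


@pytest.fixture
def logistic_profile():
    """Steep noiseless contraction with closed-form crossings and chords."""
    return LogisticProfile(f_max=50.0, k=20.0, t0=1.0, duration=4.0, noise_sd=0.0)


@pytest.fixture
def logistic_trace_1000hz(logistic_profile):
    return simulate_trace(logistic_profile, device="stable_1000hz", rng_seed=0)


@pytest.fixture
def ramp_trace_1000hz():
    """Linear ramp 0 -> 50 kg over 2 s at 1000 Hz (slope 25 kg/s)."""
    t = np.arange(0, 2.001, 0.001)
    return ForceTrace(sample_times=t, force=25.0 * t, device_profile="stable_1000hz",
                      nominal_rate=1000.0)


def brute_force_moving_window(times, force, window_ms):
    """Independent O(n*w) reference: recompute every chord explicitly."""
    dt = float(np.mean(np.diff(times)))
    w = int(round(window_ms / 1000.0 / dt))
    best = -np.inf
    best_i = -1
    for i in range(len(force) - w):
        slope = (force[i + w] - force[i]) / (w * dt)
        if slope > best:
            best = slope
            best_i = i
    return best, times[best_i]
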