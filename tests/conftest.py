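import numpy as np
import pytest

from racewalk import DetectionConfig, GaitParams, simulate_walk


@pytest.fixture
def config():
    return DetectionConfig()


@pytest.fixture
def make_walk():
    """Factory for simulated walks with overridable parameters."""

    def _make(**kwargs):
        defaults = dict(n_steps=20, overlap_time=-0.04, noise_sd=0.0, seed=11)
        defaults.update(kwargs)
        return simulate_walk(GaitParams(**defaults))

    return _make


@pytest.fixture
def clean_walk(make_walk):
    """A noise-free illegal walk (flight 0.04 s on every step)."""
    return make_walk()


def true_cycle_minima(trace, truth, params):
    """Oracle: exhaustive argmin of the vertical channel over each true cycle window."""
    period = 1.0 / params.step_rate
    t = trace.times
    out = []
    for v in truth.heel_strike_times - params.transmission_offset + truth.overlap_times:
        w = (t >= v - period / 2) & (t <= v + period / 2)
        idx = np.flatnonzero(w)
        out.append(t[idx[np.argmin(trace.vert[idx])]])
    return np.array(out)
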