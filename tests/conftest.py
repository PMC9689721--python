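import numpy as np
import pytest

from stif.benchmarks import SimulationSpec, TimeSeriesMatrix, simulate_pendulum


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_series(rng):
    """4 variables x 30 steps: AR(1)-ish smooth signals plus mixtures."""
    m = 30
    t = np.arange(m)
    base = np.sin(0.3 * t)
    vals = np.stack([
        base,
        np.cos(0.3 * t),
        0.5 * base + 0.1 * rng.standard_normal(m),
        t / m,
    ])
    return TimeSeriesMatrix(vals, ("a", "b", "c", "d"), tuple(map(float, t)))


@pytest.fixture
def pendulum_states():
    spec = SimulationSpec(system="pendulum", n_steps=50, dt=0.05, seed=3)
    return simulate_pendulum(spec)
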