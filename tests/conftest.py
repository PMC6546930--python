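import numpy as np
import pytest

from liquidens import (
    ConnectivitySpec,
    NeuronParams,
    SpikeRecord,
    build_liquid,
)


@pytest.fixture
def params():
    return NeuronParams()


@pytest.fixture
def tiny_liquid():
    """A 5-neuron liquid (4 E, 1 I) with 2 input lines, fixed seed."""
    return build_liquid(5, ConnectivitySpec(p_in_e=80, p_e_e=60, p_e_i=60, p_i_e=60), n_inputs=2, seed=7)


@pytest.fixture
def small_input():
    times = np.array([1.0, 3.5, 4.0, 10.0])
    ids = np.array([0, 1, 0, 1])
    return SpikeRecord(ids, times, duration=12.0, n_neurons=2)


def rng_spikes(n_neurons, duration, rate_hz, seed, dt=0.5):
    """Plain Bernoulli-per-step spike generator for test inputs."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    draws = rng.random((n_steps, n_neurons)) < rate_hz * dt / 1000.0
    steps, ids = np.nonzero(draws)
    return SpikeRecord(ids, steps * dt, n_steps * dt, n_neurons)
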