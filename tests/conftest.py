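import numpy as np
import pytest

from lgnpool import NeuronProfile, default_population


@pytest.fixture(scope="session")
def population():
    """Default calibrated 89-neuron population, fixed seed."""
    return default_population(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_neuron():
    """A sustained cell with a flat temporal profile (uniform rate over
    0-200 ms) and a high baseline, convenient for hand calculations."""
    return NeuronProfile(
        neuron_id="flat",
        cell_class="P",
        polarity="ON",
        baseline_rate=10.0,
        r_max=30.0,
        c50=20.0,
        hill_exponent=2.0,
        transience=0.25,
        latency_ms=0.0,
    )
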