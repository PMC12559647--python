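import numpy as np
import pytest

from caeqsim import signals, simulated_listener as sl


@pytest.fixture(scope="session")
def pink_2s():
    return signals.generate_pink_noise(2.0, seed=0)


@pytest.fixture(scope="session")
def speech_2s():
    return signals.generate_speech_surrogate(2.0, seed=1)


@pytest.fixture(scope="session")
def on1_listener():
    """A lapse-free very-mild-loss observer used across staircase tests."""
    return sl.make_listener(0, "ON1", seed=42, lapse_rate=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Study-shaped cohort: 12 ON1 + 12 ON3 listeners."""
    return sl.generate_cohort(12, ("ON1", "ON3"), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
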