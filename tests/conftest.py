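import numpy as np
import pytest

from semgkit.synthetic_data import ProtocolConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The full default-protocol dataset (10 subjects x 10 gestures x 5
    repetitions x 7 channels at 1000 Hz), generated once per session."""
    return generate_dataset(ProtocolConfig())


@pytest.fixture(scope="session")
def tiny_protocol():
    """A miniature protocol for fast pipeline tests."""
    return ProtocolConfig(
        n_subjects=2,
        n_gestures=3,
        n_repetitions=3,
        n_channels=2,
        active_duration_ms=(700.0, 1000.0),
        rest_duration_ms=1500.0,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
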