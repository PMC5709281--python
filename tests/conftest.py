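import numpy as np
import pytest

from thetawave.synthdata import SynthConfig, generate_participant


@pytest.fixture(scope="session")
def strong_dataset():
    """Full-size participant with the default strong planted theta effect."""
    return generate_participant(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """Short-segment participant for fast pipeline-level tests."""
    return generate_participant(
        SynthConfig(seed=5, segment_seconds=4.0, n_trials=12)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
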