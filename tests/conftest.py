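import numpy as np
import pytest

from cycleannot.synthio import SubjectScenario, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_subject():
    """Default walk+jog subject without sensor noise."""
    return generate_subject(SubjectScenario(seed=3, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_subject():
    """Default walk+jog subject at the default noise level."""
    return generate_subject(SubjectScenario(seed=1))


@pytest.fixture(scope="session")
def cycling_subject():
    """A 30-cycle cycling bout at the default noise level."""
    return generate_subject(SubjectScenario(seed=9, bouts=[("cycle", 30, 3.0)]))
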