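import numpy as np
import pytest

from enosekit import SensorTrace, extract_features, generate_dataset
from enosekit.synthetic import paper_like_preset, separable_preset


def make_trace(values, dt=1.0, sensor_id="S1"):
    return SensorTrace.from_values(values, dt=dt, sensor_id=sensor_id)


@pytest.fixture(scope="session")
def paper_like_set():
    """Default synthetic campaign: grades 1-5 close, grade 6 separated."""
    return generate_dataset(paper_like_preset(seed=42))


@pytest.fixture(scope="session")
def separable_set():
    """Widely spaced grades for design-controlled classifier checks."""
    return generate_dataset(separable_preset(seed=7))


@pytest.fixture(scope="session")
def paper_like_features(paper_like_set):
    return extract_features(paper_like_set)


@pytest.fixture(scope="session")
def separable_features(separable_set):
    return extract_features(separable_set)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
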