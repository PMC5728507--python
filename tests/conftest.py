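import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import swarmtune as st

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def separable_dataset() -> st.Dataset:
    """200-sample, well-separated 2-class problem (loss must fall fast)."""
    return st.make_classification_data(n=200, d=8, n_classes=2, separation=4.0, seed=11)


@pytest.fixture(scope="session")
def three_class_dataset() -> st.Dataset:
    return st.make_classification_data(n=300, d=10, n_classes=3, separation=3.0, seed=5)


@pytest.fixture(scope="session")
def qsar_dataset() -> st.Dataset:
    return st.make_qsar_data(n_molecules=300, n_descriptors=40, latent_rank=5, seed=7)


@pytest.fixture
def small_space() -> st.SearchSpace:
    """Desk-scale search box: narrow networks so evaluation stays cheap."""
    return st.SearchSpace(neuron_bounds=(8, 32), hidden_layer_count=2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
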