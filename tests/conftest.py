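import numpy as np
import pytest

from mirrorpop import synthetic_data as sd


@pytest.fixture(scope="session")
def small_session():
    """A small but complete session: 20 neurons, EMG, all conditions."""
    cfg = sd.GroundTruthConfig(
        n_neurons=20, trials_per_condition=12, latent_scale=40.0
    )
    bundle, record = sd.generate_session(cfg, seed=1234)
    return bundle, record


@pytest.fixture(scope="session")
def small_bundle(small_session):
    return small_session[0]


@pytest.fixture(scope="session")
def small_record(small_session):
    return small_session[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
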