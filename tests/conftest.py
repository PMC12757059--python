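import numpy as np
import pytest

from normnet import experiments


@pytest.fixture(scope="session")
def tiny_model():
    """Few-hundred-neuron model with calibrated V1 (shared, read-only)."""
    return experiments.build_model(scale=0.05, seed=11)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_model):
    """Three-condition run of the tiny model (2-s simulations)."""
    exp = experiments.run_normalization_experiment(
        tiny_model, duration=2000.0, n_sims=1, seed=23)
    return {"model": tiny_model, **exp}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
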