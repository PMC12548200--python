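import numpy as np
import pytest

from vqpipe.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def noise_free_config() -> PhantomConfig:
    """Default phantom with every stochastic perturbation disabled."""
    return PhantomConfig(noise_sd_hu=0.0, weight_noise_sd=0.0, fluorescence_noise_sd=0.0)


@pytest.fixture(scope="session")
def truth(noise_free_config):
    return make_phantom(noise_free_config)


@pytest.fixture(scope="session")
def olv_truth():
    return make_phantom(
        PhantomConfig(
            scenario="OLV",
            perfusion_shift=0.8,
            noise_sd_hu=0.0,
            weight_noise_sd=0.0,
            fluorescence_noise_sd=0.0,
        )
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
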