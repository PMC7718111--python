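import numpy as np
import pytest

from t1qc.phantom import AcquisitionConfig, generate_phantom
from t1qc.network import NetworkConfig, build_classifier, crop_and_stack


@pytest.fixture(scope="session")
def acq64():
    return AcquisitionConfig(image_size=64, noise_sd=0.02)


@pytest.fixture(scope="session")
def acq64_noiseless():
    return AcquisitionConfig(image_size=64, noise_sd=0.0)


@pytest.fixture(scope="session")
def case64(acq64):
    return generate_phantom(acq64, seed=42)


@pytest.fixture(scope="session")
def case64_noiseless(acq64_noiseless):
    return generate_phantom(acq64_noiseless, seed=42)


@pytest.fixture(scope="session")
def tiny_config():
    return NetworkConfig.tiny()


@pytest.fixture(scope="session")
def tiny_net(tiny_config):
    return build_classifier(tiny_config, seed=7)


@pytest.fixture(scope="session")
def model_input64(case64):
    return crop_and_stack(case64, crop_size=64)


# A micro architecture for tests that only exercise mechanics: 32² crop,
# 1/16 width.  Still 34 layers with the same depth schedule.
@pytest.fixture(scope="session")
def micro_config():
    return NetworkConfig(crop_size=32, stage_channels=(4, 8, 16, 32), stem_channels=2)


@pytest.fixture(scope="session")
def micro_net(micro_config):
    return build_classifier(micro_config, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
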