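import numpy as np
import pytest
from hypothesis import settings

from fluxmap import GroundTruth, ProtocolLayout

# derandomized hypothesis runs so the suite is reproducible everywhere
settings.register_profile("ci", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout() -> ProtocolLayout:
    return ProtocolLayout()


@pytest.fixture(scope="session")
def noiseless_truth() -> GroundTruth:
    return GroundTruth(noise_sd_PU=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
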