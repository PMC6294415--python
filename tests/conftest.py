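import numpy as np
import pytest

from tonocore.synth import (CoreTruth, NoiseModel, PatchConfig, TonotopyTruth,
                            generate_truth)
from tonocore.tuning import GaussianBank


@pytest.fixture(scope="session")
def bank():
    return GaussianBank()


@pytest.fixture(scope="session")
def default_truth():
    """Noiseless default hemisphere truth (jitter-free)."""
    return generate_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
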