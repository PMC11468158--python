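import numpy as np
import pytest

from earlyvis import filterbank as fb
from earlyvis import models as md
from earlyvis import protocol as pr


@pytest.fixture(scope="session")
def gabor_bank():
    return fb.build_bank("gabor")


@pytest.fixture(scope="session")
def dog_bank():
    return fb.build_bank("dog")


@pytest.fixture(scope="session")
def v1s_model(gabor_bank):
    return md.ModelSpec(variant="V1S", bank=gabor_bank, post_ops=("half_rectify",))


@pytest.fixture(scope="session")
def small_stimset():
    """Tiny synthetic face/non-face set shared by protocol-level tests."""
    return pr.StimulusSet.synthetic(24, seed=11, n_scenes=6)


@pytest.fixture(scope="session")
def rand_image():
    rng = np.random.default_rng(42)
    return rng.uniform(0, 255, size=(340, 340))
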