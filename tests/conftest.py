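import numpy as np
import pytest

from raunet.cascade import BoundaryBox
from raunet.phantom import PhantomConfig, generate_phantom
from raunet.preprocessing import preprocess


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic phantom: (volume, liver_mask, tumor_mask)."""
    return generate_phantom(PhantomConfig(seed=42))


@pytest.fixture(scope="session")
def preprocessed_case(phantom_case):
    """The same phantom after HU windowing + normalization, plus truth."""
    vol, liver, tumor = phantom_case
    return preprocess(vol), liver, tumor


@pytest.fixture(scope="session")
def liver_box(phantom_case):
    vol, liver, _ = phantom_case
    return BoundaryBox.from_mask(liver).expand(10, vol.data.shape)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
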