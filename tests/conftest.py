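import numpy as np
import pytest

import celldissect as cd


@pytest.fixture(scope="session")
def nuclei_fixture():
    """One synthetic nuclei field (50 objects) with ground truth, shared read-only."""
    spec = cd.ImageFixtureSpec(n_objects=50, seed=1)
    img, mask, truth = cd.make_image_fixture(spec)
    return spec, img, mask, truth


@pytest.fixture(scope="session")
def nuclei_features(nuclei_fixture):
    spec, img, mask, truth = nuclei_fixture
    return cd.extract_features(mask, {"dapi": img})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
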