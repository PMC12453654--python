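import numpy as np
import pytest

from mciic import (
    LabeledImageSet,
    SyntheticSpec,
    extract_features,
    generate,
    make_fallback_extractor,
)


@pytest.fixture(scope="session")
def default_set():
    """Default synthetic conditions: 200 majority / 10 minority, 3 modes."""
    ds, modes = generate(SyntheticSpec(seed=11))
    return ds, modes


@pytest.fixture(scope="session")
def fallback16():
    return make_fallback_extractor(16)


@pytest.fixture(scope="session")
def default_features(default_set, fallback16):
    ds, _ = default_set
    return extract_features(ds, fallback16)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
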