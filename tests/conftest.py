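import warnings

import numpy as np
import pytest

from ncsaxs import (HelixParams, build_duplex, build_released, build_wrapped,
                    generate_pool)

warnings.filterwarnings("ignore", message="superhelix arc length")


@pytest.fixture(scope="session")
def params():
    return HelixParams()


@pytest.fixture(scope="session")
def duplex149(params):
    return build_duplex(149, params)


@pytest.fixture(scope="session")
def wrapped147(params):
    return build_wrapped(147, params)


@pytest.fixture(scope="session")
def j_model(params):
    return build_released(147, 74, 0, params)


@pytest.fixture(scope="session")
def pool(params):
    return generate_pool(params=params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
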