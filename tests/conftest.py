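import numpy as np
import pytest

from lnsynapse import make_preset


@pytest.fixture(scope="session")
def cbc_fast():
    return make_preset("cbc_fast")


@pytest.fixture(scope="session")
def cbc_slow():
    return make_preset("cbc_slow")


@pytest.fixture(scope="session")
def all_presets():
    from lnsynapse import PRESET_NAMES

    return {name: make_preset(name) for name in PRESET_NAMES}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
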