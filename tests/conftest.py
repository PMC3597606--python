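import numpy as np
import pytest

from ritdose.biodist import load_packaged_table


@pytest.fixture(scope="session")
def table_12a8():
    return load_packaged_table("12A8")


@pytest.fixture(scope="session")
def table_67a2():
    return load_packaged_table("67A2")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
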