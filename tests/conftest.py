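import numpy as np
import pytest

from psptherm import bundled_table


@pytest.fixture(scope="session")
def solvents():
    return bundled_table("solvents")


@pytest.fixture(scope="session")
def drugs():
    return bundled_table("drugs")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
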