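import numpy as np
import pytest

from sbpdesign.contact_analysis import ContactCriteria
from sbpdesign.energy_model import default_params
from sbpdesign.synthetic_data import FixtureSpec, make_pocket


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def criteria():
    return ContactCriteria()


@pytest.fixture(scope="session")
def default_pocket():
    """Standard 5-contact + 2-spectator pocket around crystal-style allitol."""
    return make_pocket(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def small_pocket():
    """Two planted contacts, one spectator — cheap fixture for design tests."""
    return make_pocket(
        FixtureSpec(
            seed=2,
            contacts=[("HIS", 2.9), ("ASP", 2.8)],
            spectators=[("VAL", 3.8)],
        )
    )


@pytest.fixture(scope="session")
def design_pocket():
    """Pocket with a planted gain-of-contact site (ALA backbone that admits a
    new polar bond through one specific identity/rotamer)."""
    return make_pocket(
        FixtureSpec(
            seed=2,
            contacts=[("HIS", 2.9), ("ASP", 2.8)],
            spectators=[("VAL", 3.8)],
            designable_site=("SER", -60.0, 2.85),
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
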