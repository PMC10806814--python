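import numpy as np
import pytest

from ffport.fixtures import FixtureSpec, gen_forcefield, gen_system


@pytest.fixture(scope="session")
def ff_plain():
    return gen_forcefield(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def ff_full():
    """Force field exercising mixed SCNB and a CMAP grid."""
    return gen_forcefield(FixtureSpec(seed=2, include_mixed_scnb=True,
                                      include_cmap=True, n_residues=4))


@pytest.fixture(scope="session")
def sys_plain(ff_plain):
    return gen_system(FixtureSpec(seed=1), ff_plain)


@pytest.fixture(scope="session")
def sys_full(ff_full):
    return gen_system(FixtureSpec(seed=2, include_mixed_scnb=True,
                                  include_cmap=True, n_residues=4), ff_full)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
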