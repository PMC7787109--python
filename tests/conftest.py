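import numpy as np
import pytest

from emtable1.fixtures import FixtureSpec, build_helix, make_entry


@pytest.fixture(scope="session")
def helix10():
    return build_helix(10)


@pytest.fixture(scope="session")
def helix20():
    return build_helix(20)


@pytest.fixture(scope="session")
def entry4():
    """Clean synthetic entry with a planned 4.0 A FSC crossing."""
    return make_entry(FixtureSpec(n_residues=20, box=40.0, voxel=1.0,
                                  target_d=4.0, noise_seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
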