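import numpy as np
import pytest

from zincsite.pipeline import Structure
from zincsite.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Three-chain synthetic fixture with one planted 4-residue site per chain."""
    return generate_fixture(FixtureSpec(n_chains=3, seed=11))


@pytest.fixture(scope="session")
def small_structures(small_fixture):
    return [Structure.from_pdb_text(t) for t in small_fixture.pdb_texts.values()]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
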