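import numpy as np
import pytest
from hypothesis import settings

import mitopool as mp

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ancestor():
    return mp.make_ancestor(seed=3)


@pytest.fixture(scope="session")
def family10():
    """The default pooled study: 10 specimens at branch divergence 0.12."""
    genomes, truth = mp.make_family(mp.FamilySpec(10, 0.12, seed=1))
    return genomes, truth


@pytest.fixture(scope="session")
def pair():
    genomes, _ = mp.make_family(mp.FamilySpec(2, 0.10, seed=11))
    return genomes


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
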