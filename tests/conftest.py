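import numpy as np
import pytest

from edafold import StagedScorer
from edafold.fixtures import make_planted_library, make_toy_target
from edafold.sampling import SamplerParams

SMALL_TOPOLOGY = "HHHHHHHHHHLLHHHHHHHHHHHH"  # 24 residues, cheap tests


@pytest.fixture(scope="session")
def toy40():
    return make_toy_target(seed=0)


@pytest.fixture(scope="session")
def planted40(toy40):
    return make_planted_library(toy40, seed=0)


@pytest.fixture(scope="session")
def scorer40(toy40):
    return StagedScorer(toy40.sequence, toy40.ss_target)


@pytest.fixture(scope="session")
def toy24():
    return make_toy_target(SMALL_TOPOLOGY, seed=1)


@pytest.fixture(scope="session")
def planted24(toy24):
    return make_planted_library(toy24, seed=1)


@pytest.fixture(scope="session")
def scorer24(toy24):
    return StagedScorer(toy24.sequence, toy24.ss_target)


@pytest.fixture
def desk_params():
    return SamplerParams.desk()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
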