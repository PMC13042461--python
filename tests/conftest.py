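import numpy as np
import pytest

from latentmol.chemio import build_vocabulary, canonicalize
from latentmol.encoder import Encoder, EncoderConfig
from latentmol.synthdata import sample_library


@pytest.fixture(scope="session")
def library():
    """A deterministic 60-molecule grammar library shared across tests."""
    return sample_library(60, seed=101)


@pytest.fixture(scope="session")
def vocabulary(library):
    return build_vocabulary(library, merge_budget=16)


@pytest.fixture(scope="session")
def desk_encoder():
    return Encoder(EncoderConfig.desk(seed=11)).eval()


@pytest.fixture(scope="session")
def aspirin():
    return canonicalize("CC(=O)Oc1ccccc1C(=O)O")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
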