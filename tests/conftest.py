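import numpy as np
import pytest

from asorf.seqio import blosum62, write_matrix
from asorf.pairalign import AlignConfig


@pytest.fixture(scope="session")
def matrix():
    return blosum62()


@pytest.fixture(scope="session")
def align_cfg():
    return AlignConfig()


@pytest.fixture(scope="session")
def blosum62_file(tmp_path_factory, matrix):
    """BLOSUM62 written in NCBI/EMBOSS text layout (round-trip fixture)."""
    path = tmp_path_factory.mktemp("matrices") / "BLOSUM62.txt"
    write_matrix(path, matrix, comment="BLOSUM62 in NCBI/EMBOSS text layout")
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_protein(rng, length, alphabet="ACDEFGHIKLMNPQRSTVWY"):
    return "".join(rng.choice(list(alphabet), size=length))


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))
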