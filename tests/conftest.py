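import numpy as np
import pytest

from aarcode.seqio import Proteome
from aarcode.synthetic_data import ProteomeSpec, gen_proteome
from aarcode.workflows import DEFAULT_P_INSERT


@pytest.fixture
def tiny_proteome() -> Proteome:
    """Four proteins with presence sets {A,Q}, {A}, {}, {Q}."""
    return Proteome(
        "tiny",
        (
            ("p1", "MAAAAKQQQQW"),
            ("p2", "MAAAAKW"),
            ("p3", "MKWC"),
            ("p4", "QQQQQW"),
        ),
    )


@pytest.fixture(scope="session")
def synthetic_proteome():
    """A seeded 400-protein synthetic proteome with its ground truth."""
    spec = ProteomeSpec(n_proteins=400, p_insert=DEFAULT_P_INSERT, seed=20240901)
    return gen_proteome(spec)


@pytest.fixture
def write_fasta_file(tmp_path):
    def _write(text: str, name: str = "test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(991)
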