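import numpy as np
import pytest

from transannot.seq_core import SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_nt(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


@pytest.fixture
def toy_orthologs():
    return [
        SequenceRecord("ORTH1", "MKC", meta={"gene_symbol": "G1"}),
        SequenceRecord("ORTH2", "MVDEQRSTLL", meta={"gene_symbol": "G2"}),
    ]
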