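import numpy as np
import pytest

from discretus.io_core import SequenceRecord, UltrametricTree


@pytest.fixture
def simple_tree() -> UltrametricTree:
    return UltrametricTree.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4_tree() -> UltrametricTree:
    return UltrametricTree.from_newick_string(
        "((A:1,B:1):2,(C:2,D:2):1);"
    )


@pytest.fixture
def tiny_alignment() -> list[SequenceRecord]:
    return [
        SequenceRecord("A", "AAAA"),
        SequenceRecord("B", "AAAT"),
        SequenceRecord("C", "AATT"),
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
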