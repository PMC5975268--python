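import pytest

from tdrlkit import CircularGeneOrder
from tdrlkit.datasets import psocoptera_pair, toy_pair

#: the sixteen equivalent TDRLs of the eight-gene worked example, as
#: (F, origin) pairs of the quoted labeling (S is the complement)
TOY_PRINTED_TRIPLES = {
    (frozenset({3, 5, 7, 8}), 1),
    (frozenset({1, 3, 5, 7, 8}), 2),
    (frozenset({4, 6}), 3),
    (frozenset({1, 2, 5, 7, 8}), 4),
    (frozenset({3, 6}), 5),
    (frozenset({1, 2, 4, 7, 8}), 6),
    (frozenset({3, 5}), 7),
    (frozenset({3, 5, 7}), 8),
}


@pytest.fixture(scope="session")
def toy_source():
    return toy_pair()[0]


@pytest.fixture(scope="session")
def toy_target():
    return toy_pair()[1]


@pytest.fixture(scope="session")
def fig1_order():
    return CircularGeneOrder((1, 4, 2, 5, 3))


@pytest.fixture(scope="session")
def psocoptera():
    """(ancestral, rearranged) case-study orders (synthetic reconstruction)."""
    return psocoptera_pair()
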