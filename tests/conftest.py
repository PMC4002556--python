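import numpy as np
import pytest

from ordagree import ContingencyTable, PairedAssessments


@pytest.fixture
def uniform5():
    """5×5 table with one subject in every cell (n = 25)."""
    return ContingencyTable(np.ones((5, 5), dtype=int))


@pytest.fixture
def uniform2():
    return ContingencyTable(np.ones((2, 2), dtype=int))


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


def make_pairs(tuples, **kw):
    return PairedAssessments.from_tuples(tuples, **kw)


@pytest.fixture
def pairs_factory():
    return make_pairs
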