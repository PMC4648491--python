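import numpy as np
import pytest

from smartddpcr import fixtures


@pytest.fixture(scope="session")
def table1_counts():
    return fixtures.load_table1_counts()


@pytest.fixture(scope="session")
def table2_candidates():
    return fixtures.table2_candidates()


@pytest.fixture(scope="session")
def cancer_vocab():
    return fixtures.load_cancer_vocab()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
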