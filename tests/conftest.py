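import numpy as np
import pytest

from dabnet import worked_example_fixture, worked_example_matrix


@pytest.fixture(scope="session")
def worked_matrix():
    return worked_example_matrix()


@pytest.fixture(scope="session")
def worked_states():
    relations, states = worked_example_fixture()
    return relations, states


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
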