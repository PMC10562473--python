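import numpy as np
import pytest

from pssk import datasets
from pssk.sequences import PhosphoPattern


@pytest.fixture(scope="session")
def ki67():
    return datasets.ki67_consensus_repeat()


@pytest.fixture(scope="session")
def ki67_sites():
    return datasets.ki67_repeat_phosphosites()


@pytest.fixture(scope="session")
def ki67_full_pattern(ki67_sites):
    return PhosphoPattern(tuple(ki67_sites), frozenset(ki67_sites))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
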