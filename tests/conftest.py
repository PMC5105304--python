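import numpy as np
import pytest

from tipcall.consensus import default_consensus


@pytest.fixture(scope="session")
def consensus():
    return default_consensus()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251002)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
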