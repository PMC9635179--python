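import numpy as np
import pytest

from strscape.abundance import load_fixture
from strscape.cluster_stats import reference_partition


@pytest.fixture(scope="session")
def mono():
    return load_fixture("mono")


@pytest.fixture(scope="session")
def di():
    return load_fixture("di")


@pytest.fixture(scope="session")
def tri():
    return load_fixture("tri")


@pytest.fixture(scope="session")
def fixtures_by_category(mono, di, tri):
    return {"mono": mono, "di": di, "tri": tri}


@pytest.fixture(scope="session")
def reference():
    return reference_partition()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_sequence(rng, length, alphabet="ACGT", p=None):
    return "".join(rng.choice(list(alphabet), p=p, size=length))
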