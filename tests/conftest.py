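import pytest

import avnscreen as avn


@pytest.fixture(scope="session")
def roster():
    return avn.enumerate_collection()


@pytest.fixture(scope="session")
def by_code(roster):
    return {e.code: e for e in roster}


@pytest.fixture(scope="session")
def desc_table(roster):
    return avn.compute_table(roster)


@pytest.fixture(scope="session")
def score_table():
    return avn.read_score_table()


@pytest.fixture(scope="session")
def pains():
    return avn.load_catalog("PAINS")


@pytest.fixture(scope="session")
def brenk():
    return avn.load_catalog("BRENK")


@pytest.fixture(scope="session")
def descriptors_by_code(roster):
    return {e.code: avn.compute_all(e.mol()) for e in roster}
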