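import pytest

from ovoclone import datasets


@pytest.fixture(scope="session")
def marcm_0hr():
    return datasets.marcm_0hr()


@pytest.fixture(scope="session")
def marcm_36hr():
    return datasets.marcm_36hr()


@pytest.fixture(scope="session")
def multicolor_0hr():
    return datasets.multicolor_0hr()


@pytest.fixture(scope="session")
def bond_gal4():
    return datasets.bond_gal4()
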