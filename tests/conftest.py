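import pytest

from cypcocktail import synthetic


@pytest.fixture(scope="session")
def kb():
    return synthetic.fixture_tables_kb()


@pytest.fixture()
def regimen_initial():
    return synthetic.fixture_regimen_initial()


@pytest.fixture()
def regimen_optimized():
    return synthetic.fixture_regimen_optimized()
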