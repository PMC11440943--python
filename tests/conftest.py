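import pytest

from smncall import build_default_model


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def table1(model):
    from smncall.datasets import load_table1_genotypes

    return load_table1_genotypes()


@pytest.fixture(scope="session")
def table2():
    from smncall.datasets import load_table2_discordant

    return load_table2_discordant()
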