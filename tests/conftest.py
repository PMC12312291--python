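import pytest

from oscifluor import ModelParameters, genotype_preset


@pytest.fixture(scope="session")
def wt():
    return genotype_preset("WT")


@pytest.fixture(scope="session")
def defaults():
    return ModelParameters()
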