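import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mpsscore import make_toy_bundle, table1_dataset
from mpsscore.fixtures import ToyBundleSpec


@pytest.fixture(scope="session")
def catalogue():
    return table1_dataset()


@pytest.fixture(scope="session")
def toy():
    """(bundle, truth_map) for the synthetic toy protein."""
    return make_toy_bundle(ToyBundleSpec())


@pytest.fixture(scope="session")
def toy_bundle(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]
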