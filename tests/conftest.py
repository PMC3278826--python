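import pytest

from glapred.sequence_data import WindowConfig, extract_all_fragments
from glapred.synthetic import GeneratorSpec, generate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic benchmark, fixed seed, shared across tests."""
    return generate(GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def window():
    return WindowConfig(7)


@pytest.fixture(scope="session")
def fragments(dataset, window):
    return extract_all_fragments(dataset.records, window)


@pytest.fixture(scope="session")
def positive_fragments(fragments):
    return [f for f in fragments if f.is_positive]


@pytest.fixture(scope="session")
def negative_fragments(fragments):
    return [f for f in fragments if not f.is_positive]


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter benchmark for the slower end-to-end checks."""
    return generate(GeneratorSpec(n_proteins=30, seed=7))
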