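import pytest

from organoidqc import default_scheme
from organoidqc.io import evaluate_table, example_scores


@pytest.fixture(scope="session")
def final_scheme():
    return default_scheme("final")


@pytest.fixture(scope="session")
def initial_scheme():
    return default_scheme("initial")


@pytest.fixture(scope="session")
def example_table():
    return example_scores()


@pytest.fixture(scope="session")
def example_cards(example_table, final_scheme):
    return evaluate_table(example_table, final_scheme)
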