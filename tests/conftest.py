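import pytest

from transpt.floors import default_registry
from transpt.scoring import default_model
from transpt.synthetic import dataset1_like_records


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def mutant_panel(registry, model):
    """11 templates + 27 graded single-floor mutants (n = 38)."""
    return dataset1_like_records(registry, model)
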