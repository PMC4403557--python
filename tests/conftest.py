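import pytest

from vitasynth.predict import RuleSet
from vitasynth.supply import default_cell_model, default_supply_parameters


@pytest.fixture(scope="session")
def rules() -> RuleSet:
    return RuleSet.default()


@pytest.fixture(scope="session")
def cell():
    return default_cell_model()


@pytest.fixture(scope="session")
def supply_params():
    return default_supply_parameters()
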