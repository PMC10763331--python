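import pytest

from methyloflux import build_core_model, run_scenario_matrix


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def scenario_table(core_model):
    """The full 3-product x 5-scenario yield grid (15 LP families)."""
    return run_scenario_matrix(core_model)
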