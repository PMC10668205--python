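import pytest

from htncea.engine import RunConfig
from htncea.parameters import load_default_parameters


@pytest.fixture(scope="session")
def base_params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def base_inputs(base_params):
    return base_params.to_inputs()


@pytest.fixture()
def cfg15():
    return RunConfig(horizon_years=15)


@pytest.fixture()
def cfg8():
    return RunConfig(horizon_years=8)
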