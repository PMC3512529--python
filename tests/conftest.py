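import pytest

from il2x import default_params
from il2x.model_core import CellParams, MediumParams


@pytest.fixture(scope="session")
def default_cell() -> CellParams:
    return default_params()[0]


@pytest.fixture(scope="session")
def default_medium() -> MediumParams:
    return default_params()[1]
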