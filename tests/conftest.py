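import numpy as np
import pytest

from t1dvpp.model import ParameterBatch
from t1dvpp.parameters import ModelParameters
from t1dvpp.population import titrate_basal


@pytest.fixture(scope="session")
def nominal_sh() -> ModelParameters:
    return ModelParameters(mode="SH")


@pytest.fixture(scope="session")
def nominal_dh() -> ModelParameters:
    return ModelParameters(mode="DH")


@pytest.fixture(scope="session")
def nominal_basal(nominal_sh) -> float:
    """Titrated basal (mU/kg/min) for the nominal patient; shared because
    titration runs many 48-h simulations."""
    return titrate_basal(nominal_sh)


@pytest.fixture(scope="session")
def nominal_batch(nominal_sh) -> ParameterBatch:
    return ParameterBatch.from_params([nominal_sh])


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
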