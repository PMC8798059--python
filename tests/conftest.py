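import numpy as np
import pytest

from mtdynamics import KineticParams, load_default_params


@pytest.fixture(scope="session")
def default_params() -> dict[str, KineticParams]:
    return load_default_params()


@pytest.fixture(scope="session")
def control(default_params) -> KineticParams:
    return default_params["control"]


@pytest.fixture(scope="session")
def ckap2_500(default_params) -> KineticParams:
    return default_params["ckap2_500nM"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
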