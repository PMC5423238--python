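import numpy as np
import pytest

from zcspec import NoiseModel, WavelengthGrid, default_analyte_models


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()  # 200-350 nm, 0.1 nm step


@pytest.fixture(scope="session")
def models():
    return default_analyte_models()


@pytest.fixture()
def noise_free():
    return NoiseModel(sd_au=0.0, baseline_drift_au=0.0, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
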