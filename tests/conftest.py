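import numpy as np
import pytest

from palbocea import ModelSettings, ParametricSurvivalModel, default_config

# Published Weibull (scale, shape) inputs per arm and endpoint
TABLE_WEIBULL = {
    ("palbociclib", "pfs"): (0.06497, 0.95501),
    ("palbociclib", "os"): (0.00656, 1.30497),
    ("placebo", "pfs"): (0.1405, 0.8904),
    ("placebo", "os"): (0.00727, 1.34619),
}


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def settings():
    return ModelSettings()


@pytest.fixture
def palbo_pfs():
    return ParametricSurvivalModel("weibull", *TABLE_WEIBULL[("palbociclib", "pfs")])


@pytest.fixture
def placebo_pfs():
    return ParametricSurvivalModel("weibull", *TABLE_WEIBULL[("placebo", "pfs")])


@pytest.fixture
def rng():
    return np.random.default_rng(20230314)
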