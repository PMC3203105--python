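import numpy as np
import pytest

import pmslt


@pytest.fixture(scope="session")
def world():
    w = pmslt.default_world(seed=1)
    pmslt.validate_world(w)
    return w


@pytest.fixture(scope="session")
def prepared(world):
    return pmslt.PreparedWorld(world)


@pytest.fixture(scope="session")
def sibutramine_point(prepared):
    return pmslt.evaluate_scenario(prepared, pmslt.ScenarioConfig(drug="sibutramine"))


@pytest.fixture(scope="session")
def orlistat_point(prepared):
    return pmslt.evaluate_scenario(prepared, pmslt.ScenarioConfig(drug="orlistat"))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20030101)
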