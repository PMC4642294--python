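import numpy as np
import pytest

from pamdensity import presets
from pamdensity.detection import (SimConfig, simulate_click_detection,
                                  simulate_group_detection)

# Monte Carlo sizes for the test suite: 100 iterations x 5,000 placements
# keeps every detection function under a couple of seconds while leaving
# the disc-averaged probabilities stable to ~+/-0.002.
SIM = SimConfig(iterations=100, animals_per_iteration=5000, seed=20100502)


@pytest.fixture(scope="session")
def cuviers_scenario():
    return presets.cuviers_gom()


@pytest.fixture(scope="session")
def gervais_scenario():
    return presets.gervais_gom()


@pytest.fixture(scope="session")
def cuviers_click_detfun(cuviers_scenario):
    return simulate_click_detection(cuviers_scenario, SIM)


@pytest.fixture(scope="session")
def cuviers_group_detfun(cuviers_scenario):
    return simulate_group_detection(cuviers_scenario, presets.default_behavior(), SIM)


@pytest.fixture(scope="session")
def gervais_click_detfun(gervais_scenario):
    return simulate_click_detection(gervais_scenario, SIM)


@pytest.fixture(scope="session")
def gervais_group_detfun(gervais_scenario):
    return simulate_group_detection(gervais_scenario, presets.default_behavior(), SIM)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
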