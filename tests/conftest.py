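import numpy as np
import pytest

from emuflux.emu import decompose
from emuflux.fixtures import (
    full_emu_targets,
    rich_network,
    rich_scenario,
    toy_network,
    toy_scenario,
    washout_network,
)
from emuflux.predictors import SimulatorPredictor


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def rich_net():
    return rich_network()


@pytest.fixture(scope="session")
def washout_net():
    return washout_network()


@pytest.fixture(scope="session")
def toy_sc():
    return toy_scenario()


@pytest.fixture(scope="session")
def rich_sc():
    return rich_scenario()


@pytest.fixture(scope="session")
def toy_oracle(toy_sc):
    return SimulatorPredictor(toy_sc.emu_network, toy_sc.timepoints)


@pytest.fixture(scope="session")
def rich_oracle(rich_sc):
    return SimulatorPredictor(rich_sc.emu_network, rich_sc.timepoints)
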