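import numpy as np
import pytest

from biogeoclim.areas import AreaScheme, FIVE_REGIONS
from biogeoclim.occurrences import collapse_localities
from biogeoclim.simulate import (SimulationConfig, triassic_survey_grids,
                                 triassic_survey_occurrences, simulate_tree)
from biogeoclim.statespace import build_state_space
from biogeoclim.trees import parse_newick


@pytest.fixture(scope="session")
def scheme2():
    return AreaScheme(labels=("A", "B"))


@pytest.fixture(scope="session")
def scheme3():
    return AreaScheme(labels=("A", "B", "C"))


@pytest.fixture(scope="session")
def space2(scheme2):
    return build_state_space(scheme2)


@pytest.fixture(scope="session")
def space3(scheme3):
    return build_state_space(scheme3)


@pytest.fixture(scope="session")
def space5():
    return build_state_space(FIVE_REGIONS)


@pytest.fixture(scope="session")
def tree2():
    return parse_newick("(x:4,y:7);", root_age=7)


@pytest.fixture(scope="session")
def tree3():
    return parse_newick("((x:2,y:2):3,z:5);", root_age=5)


@pytest.fixture(scope="session")
def mimic_records():
    return triassic_survey_occurrences()


@pytest.fixture(scope="session")
def mimic_collapsed(mimic_records):
    return collapse_localities(mimic_records)


@pytest.fixture(scope="session")
def mimic_grids():
    return triassic_survey_grids()


@pytest.fixture(scope="session")
def small_tree():
    cfg = SimulationConfig(seed=11, n_tips=20)
    return simulate_tree(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
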