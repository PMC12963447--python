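import pandas as pd
import pytest

from morbinet import codemap as cm
from morbinet import index as ix
from morbinet import simulate as sim

GRID = [pd.Timestamp(y, 1, 1) for y in range(2013, 2023)]
END_DATE = pd.Timestamp("2022-12-31")


@pytest.fixture(scope="session")
def sim_config():
    return sim.default_config(n_patients=3000, seed=11)


@pytest.fixture(scope="session")
def cohort(sim_config):
    patients, events = sim.generate_cohort(sim_config)
    return patients, events


@pytest.fixture(scope="session")
def mapped_events(sim_config, cohort):
    _, events = cohort
    codemap = sim.codemap_from_config(sim_config)
    mapped, _ = cm.map_events(events, codemap)
    return mapped


@pytest.fixture(scope="session")
def weights(sim_config):
    return sim.weights_from_config(sim_config)


@pytest.fixture(scope="session")
def codemap(sim_config):
    return sim.codemap_from_config(sim_config)


@pytest.fixture(scope="session")
def index_table(cohort, mapped_events, weights):
    patients, _ = cohort
    return ix.cohort_index_table(patients, mapped_events, weights, GRID)


@pytest.fixture(scope="session")
def thresholds(index_table):
    ref = index_table.loc[index_table["date"] == GRID[-1], "index"]
    return ix.compute_thresholds(ref)
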