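import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tactile_avatar import (
    SimulationConfig,
    build_material_library,
    decision_histograms,
    sample_participant,
    simulate_decision_matrix,
)
from tactile_avatar.model import TactileAvatarModel

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

SMALL_M = 12


@pytest.fixture(scope="session")
def small_library():
    return build_material_library(SMALL_M, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_materials=SMALL_M, n_trials_per_material=10, seed=8)


@pytest.fixture(scope="session")
def participant_s():
    return sample_participant("S", SMALL_M, seed=9)


@pytest.fixture(scope="session")
def matrix_s(participant_s):
    return simulate_decision_matrix(participant_s, n_trials=20)


@pytest.fixture(scope="session")
def small_model(small_library, small_config, matrix_s):
    return TactileAvatarModel.from_corpus(small_library, small_config, matrix_s)


@pytest.fixture(scope="session")
def fitted_histogram(small_model):
    return small_model.fit(mode="histogram", epochs=25, seed=10)


@pytest.fixture(scope="session")
def fitted_categorical(small_model):
    return small_model.fit(mode="categorical", epochs=25, seed=10)
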