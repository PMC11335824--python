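import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from forensicsdt import ExperimentDesign, default_group_params, simulate_experiment
from forensicsdt.fixtures import expert_study_records, novice_study_records


@pytest.fixture(scope="session")
def expert_records() -> pd.DataFrame:
    return expert_study_records()


@pytest.fixture(scope="session")
def novice_records() -> pd.DataFrame:
    return novice_study_records()


@pytest.fixture(scope="session")
def small_dataset() -> pd.DataFrame:
    """A small simulated expert/novice dataset (5 replicates, 8+8 participants)."""
    design = ExperimentDesign(n_participants_per_group=8, n_replicates=5)
    return simulate_experiment(default_group_params(), design, seed=123)
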