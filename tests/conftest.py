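import numpy as np
import pytest
from hypothesis import settings

from foragebold import design_matrix as dm
from foragebold import synth_bold as sb
from foragebold import task_schedule as ts
from foragebold import td_model as td

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_schedule():
    return ts.generate_schedule(ts.TaskConfig(seed=11))


@pytest.fixture(scope="session")
def exp3_schedule():
    return ts.generate_schedule(ts.experiment_task_config(3, seed=11))


@pytest.fixture(scope="session")
def exp1_sim():
    """Trained model, recorded trace and curves for the irregular task."""
    return td.simulate_experiment(1, td_config=td.TDConfig(seed=5))


@pytest.fixture(scope="session")
def exp2_sim():
    return td.simulate_experiment(2, td_config=td.TDConfig(seed=5))


@pytest.fixture(scope="session")
def exp3_sim():
    return td.simulate_experiment(3, td_config=td.TDConfig(seed=5))


@pytest.fixture(scope="session")
def block_design(default_schedule):
    return dm.build_block_design(default_schedule, tr=2.46, n_scans=144)


@pytest.fixture(scope="session")
def phantom():
    return sb.default_phantom()
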