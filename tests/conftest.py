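import pytest

from stressmir.pipeline import run_synthetic_pipeline, score_against_truth
from stressmir.synthetic_data import SimulationConfig


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    """One full synthetic run at the default configuration, shared."""
    return run_synthetic_pipeline(default_config)


@pytest.fixture(scope="session")
def pipeline_scores(pipeline_result):
    return score_against_truth(pipeline_result)
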