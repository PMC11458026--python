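import numpy as np
import pytest

from plankgrid.config import PipelineConfig
from plankgrid.pipeline import run_pipeline
from plankgrid.synth import scenario_default, simulate_survey


@pytest.fixture(scope="session")
def default_sim():
    """Datasets, environment table and ground truth of the reference scenario."""
    return simulate_survey(scenario_default())


@pytest.fixture(scope="session")
def pipeline_default():
    """One full pipeline run (with inter-annual stage) at the default config."""
    return run_pipeline(PipelineConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
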