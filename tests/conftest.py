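import numpy as np
import pandas as pd
import pytest

from nedmr import PipelineConfig, SimulationConfig, run_pipeline
from nedmr.simulate import generate_annotation, simulate_methylation


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def annotation_truth(small_config):
    return generate_annotation(small_config)


@pytest.fixture(scope="session")
def methylation(annotation_truth):
    annotation, truth = annotation_truth
    beta, groups = simulate_methylation(annotation, truth)
    return beta, groups


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run shared across integration-level tests."""
    return run_pipeline(PipelineConfig(seed=11))


def toy_beta(values: dict, samples: list) -> pd.DataFrame:
    return pd.DataFrame(values, index=samples).T


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
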