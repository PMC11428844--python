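import warnings

import numpy as np
import pytest

from scvgatae.config import RunConfig
from scvgatae.pipeline import run_pipeline
from scvgatae.synthetic import SimulationSpec, generate_counts

# the NE chain legitimately warns about empty transition columns on sparse
# similarity rows; keep test output clean
warnings.filterwarnings("ignore", message=".*empty transition columns.*")
warnings.filterwarnings("ignore", message=".*isolated cells.*")


@pytest.fixture(scope="session")
def study_spec():
    """The default simulation: 300 cells, 1000 genes, 3 clusters, 30% dropout."""
    return SimulationSpec()


@pytest.fixture(scope="session")
def study_counts():
    """Counts + planted labels for the default spec at seed 0."""
    return generate_counts(SimulationSpec(seed=0))


@pytest.fixture(scope="session")
def pipeline_runs():
    """Full default pipeline runs on the study spec, seeds 0..2 (shared across
    the training-behavior and recovery tests to keep the suite fast)."""
    runs = {}
    for seed in (0, 1, 2):
        counts, labels = generate_counts(SimulationSpec(seed=seed))
        runs[seed] = run_pipeline(counts, RunConfig(seed=seed), labels)
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
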