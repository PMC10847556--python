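import numpy as np
import pytest

from pcgscreen import pipeline, synth


@pytest.fixture(scope="session")
def small_cohort():
    """40-participant cohort for fast structural tests."""
    cfg = synth.CohortConfig(n_participants=40, seed=7)
    participants, truth = synth.generate_cohort(cfg)
    return cfg, participants, truth


@pytest.fixture(scope="session")
def study_cohort():
    """The seeded 400-participant cohort used by the end-to-end checks."""
    cfg = synth.CohortConfig(n_participants=400, seed=2024)
    participants, truth = synth.generate_cohort(cfg)
    return cfg, participants, truth


@pytest.fixture(scope="session")
def study_dataset(study_cohort):
    """Segmented + featurized block dataset of the 400-participant cohort.

    Built once per session; murmur-net training tests and the cross-
    validation harness both reuse it.
    """
    cfg, participants, truth = study_cohort
    dataset = pipeline.build_block_dataset(participants, cfg.sample_rate_hz)
    return dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
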