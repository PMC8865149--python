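"""Shared fixtures: a small simulated cohort and its extracted features."""

import pytest

from phenotrack.config import SimConfig
from phenotrack.pipeline import extract_features
from phenotrack.simulate import simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_per_group={"HC": 1, "MDD": 1, "BP": 1, "SCZ": 1},
                     dropout_frac=0.0, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return extract_features(small_cohort)
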