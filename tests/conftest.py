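"""Shared fixtures: all datasets are generated programmatically."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from leap.config import CohortConfig, SignalModel
from leap.synthetic import generate_cohort, generate_plate_reads
from leap.quantitation import build_feature_matrix


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def default_reads(default_cohort):
    return generate_plate_reads(default_cohort, SignalModel(), seed=12)


@pytest.fixture(scope="session")
def default_features(default_cohort, default_reads):
    return build_feature_matrix(default_reads, default_cohort)


def small_cohort_config(**overrides) -> CohortConfig:
    base = dict(n_donors=90, cancer_count=27, triplicate_count=24, seed=3)
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="session")
def small_features():
    """A compact cohort for classifier tests (90 donors, 114 assays)."""
    donors = generate_cohort(small_cohort_config(), seed=21)
    reads = generate_plate_reads(donors, SignalModel(), seed=22)
    return build_feature_matrix(reads, donors)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*strata have fewer than 3 donors.*"
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
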