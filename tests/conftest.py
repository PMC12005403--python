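"""Shared fixtures: small synthetic cohorts sized for fast unit tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from magtrack.simulate import CohortBundle, SyntheticCohortParams, make_bundle

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: desk-scale parameters small enough for sub-second alignment
SMALL = dict(n_genomes=2, genome_length=5_000, read_length=100, n_reads=2_000)


@pytest.fixture(scope="session")
def small_bundle() -> CohortBundle:
    """Disjoint donor/patient sources, error-free reads."""
    return make_bundle(SyntheticCohortParams(seed=101, **SMALL))


@pytest.fixture(scope="session")
def shared_bundle() -> CohortBundle:
    """Donor and patient share 30% of genome content, error-free reads."""
    return make_bundle(SyntheticCohortParams(seed=202, shared_fraction=0.3, **SMALL))


@pytest.fixture(scope="session")
def noisy_bundle() -> CohortBundle:
    """Disjoint sources with 0.5% per-base substitution error."""
    return make_bundle(SyntheticCohortParams(seed=303, error_rate=0.005, **SMALL))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
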