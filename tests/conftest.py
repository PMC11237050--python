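"""Shared fixtures: small simulated cohorts and subjects.

Expensive simulations are session-scoped so the suite builds each cohort
once.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from dexin import CohortConfig, FingerIndividuation, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    return CohortConfig(n_patients=2, n_controls=2, blocks=2, seed=101)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = simulate_cohort(small_config)
    return cohort, truth


@pytest.fixture(scope="session")
def noise_free_subject():
    """One control subject with every stochastic trial term switched off."""
    config = CohortConfig(n_patients=0, n_controls=1, blocks=2, seed=7).noise_free()
    cohort, truth = simulate_cohort(config)
    subject = cohort.subjects[0]
    return subject, truth[subject.subject_id]


@pytest.fixture(scope="session")
def default_results():
    """Fitted results for a full-design default-noise cohort (11 + 7,
    10 blocks) with ground truth attached; shared across recovery,
    reliability and clinical tests."""
    model = FingerIndividuation.from_simulation(CohortConfig(seed=42))
    return model.fit()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
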