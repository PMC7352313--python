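"""Shared fixtures: small seeded cohorts and fast model profiles."""

import numpy as np
import pytest

from seropanel import CohortConfig, generate_cohort, log_transform_markers

#: Fast model profile for tests that exercise the full five-algorithm suite:
#: a small forest and a fixed ridge penalty keep fits quick without changing
#: any contract under test.
FAST_MODELS = {"n_trees": 12, "ridge_C": 1.0, "svm_tol": 1e-2}


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (180 cases / 573 controls, seed 1)."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def default_cohort_log(default_cohort):
    return log_transform_markers(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort over four markers for cheap end-to-end runs."""
    markers = ("ApoA1", "CA125", "CA19-9", "CEA")
    cfg = CohortConfig(
        n_case=60,
        n_control=120,
        marker_names=markers,
        effect_shift={m: 1.5 for m in markers},
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
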