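import numpy as np
import pytest

from reachml import (
    SubjectProfile,
    make_target_layout,
    prepare_dataset,
    simulate_cohort,
)

#: Fixed seed for the shared synthetic cohorts.
COHORT_SEED = 42


@pytest.fixture(scope="session")
def healthy_profile():
    return SubjectProfile(
        subject_id="H01",
        condition="healthy",
        handedness="R",
        limb_length=750.0,
        mean_movement_duration=2.2,
        pathology_severity=0.0,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def layout(healthy_profile):
    return make_target_layout(
        healthy_profile.limb_length, healthy_profile.acromion_height
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2 subjects per condition, 2 cycles per arm: 216 recordings.

    Two cycles keep stratified 85% splits feasible even for the 18-class
    intention-prediction label scheme (test split must cover every class).
    """
    recordings, manifest = simulate_cohort(2, 2, 2, 2, seed=11)
    return recordings, manifest


@pytest.fixture(scope="session")
def default_cohort():
    """The reference cohort: 10 healthy, 11 LHD, 10 RHD; 3 cycles per arm."""
    recordings, manifest = simulate_cohort(10, 11, 10, 3, seed=COHORT_SEED)
    return recordings, manifest


@pytest.fixture(scope="session")
def default_prepared(default_cohort):
    recordings, _ = default_cohort
    return prepare_dataset(recordings)
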