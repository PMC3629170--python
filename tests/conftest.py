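import numpy as np
import pytest

from tissuemrs import (
    ArtifactModel,
    CohortDesign,
    EffectModel,
    generate_cohort,
    preprocess_pipeline,
)
from tissuemrs.synthetic import Stratum, default_axis

# coarse grid for unit tests; the default fine grid is exercised by the
# full-cohort fixtures and the acceptance tests
SMALL_STEP = 5e-3


@pytest.fixture(scope="session")
def small_axis():
    return default_axis(step=SMALL_STEP)


def small_design(seed: int = 5) -> CohortDesign:
    """60 samples / 45 patients, two strata; cheap stand-in cohort."""
    return CohortDesign(
        strata=(
            Stratum("normal", 20, 15, 0.0, 0.0, "constant"),
            Stratum("tc_gt5", 40, 30, 7.0, 95.0, "skewed"),
        ),
        n_patients=45,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort(small_axis):
    return generate_cohort(small_design(), axis=small_axis)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    spectra, meta = small_cohort
    return preprocess_pipeline(spectra), meta


@pytest.fixture(scope="session")
def full_cohort():
    """Default study-design cohort: 328 samples / 228 patients, fine grid."""
    return generate_cohort(CohortDesign(seed=0))


@pytest.fixture(scope="session")
def full_preprocessed(full_cohort):
    spectra, meta = full_cohort
    return preprocess_pipeline(spectra), meta
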