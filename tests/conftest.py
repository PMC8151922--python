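import numpy as np
import pytest

from renotex import ClassLabel, CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """A miniature cohort: 4/3/3 kidneys, default geometry, fixed seed."""
    return CohortSpec(
        counts={ClassLabel.NORMAL: 4, ClassLabel.MILD_MODERATE: 3, ClassLabel.SEVERE: 3},
        seed=20240501,
    )


@pytest.fixture(scope="session")
def small_records(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
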