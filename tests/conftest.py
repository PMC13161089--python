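import numpy as np
import pytest

from cmipipe.synthetic import CohortSpec, TaskGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return TaskGeometry()


@pytest.fixture
def clean_spec():
    """All noise and injection probabilities off: deterministic trials."""
    return CohortSpec(
        n_participants=2,
        seed=1,
        error_probability=0.0,
        endpoint_noise_sd=0.0,
        endpoint_bias_sd=0.0,
        position_noise_sd=0.0,
        dr_probability={"standard": 0.0, "pc_fr": 0.0},
        correction_probability={"standard": 0.0, "pc_fr": 0.0},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One small default-condition cohort shared across read-only tests."""
    from cmipipe.synthetic import generate_cohort

    return generate_cohort(
        CohortSpec(seed=42, n_participants=10),
        timeseries_T=200,
        tract_length=40,
    )
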