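import numpy as np
import pytest

from catchmsi.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A small but well-conditioned cohort: 100 samples, 4x4 tensor, 5 genes."""
    return SimulationConfig(n_cases=25, control_ratio=3, d1=4, d2=4, q=5,
                            s=3, delta=1.0, alpha_density=0.2,
                            alpha_scale=0.4, covariate_shift=1.0, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    cohort, truth = generate_cohort(small_config)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, d, jitter=3.0):
    A = rng.standard_normal((d, d))
    return A @ A.T + jitter * np.eye(d)
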