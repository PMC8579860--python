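import numpy as np
import pytest

from vimtarget import GeneratorConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_cohort():
    """15 patients, one unilateral (29 leads), realistic noise levels."""
    return generate_cohort(GeneratorConfig(n_patients=15, n_unilateral=1, seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small noiseless cohort: exact landmarks, exact targets."""
    return generate_cohort(
        GeneratorConfig(n_patients=20, n_unilateral=0, seed=7,
                        observer_sigma=0.0, implantation_sigma=0.0)
    )
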