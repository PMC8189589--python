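import numpy as np
import pytest

from striacov.synthetic import generate_paired_cohort


@pytest.fixture(scope="session")
def planted_cohort():
    """A small cohort with a strong planted mode (rho = 0.8)."""
    return generate_paired_cohort(
        n_roi_vox=150, n_brain_vox=300, planted_rho=0.8, seed=7
    )


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no cross-modal mode (rho = 0)."""
    return generate_paired_cohort(
        n_roi_vox=60, n_brain_vox=120, planted_rho=0.0, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
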