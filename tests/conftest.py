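import numpy as np
import pytest

from gascreen import CohortConfig, ScanGeometry, generate_cohort, load_bundled_criteria


@pytest.fixture(scope="session")
def geom():
    """Default macular-cube geometry: 128 x 512 over 6 x 6 mm."""
    return ScanGeometry()


@pytest.fixture(scope="session")
def horizon():
    return load_bundled_criteria("horizon")


@pytest.fixture(scope="session")
def gather2():
    return load_bundled_criteria("gather2")


@pytest.fixture(scope="session")
def small_cohort(horizon):
    """60-patient seeded cohort with HORIZON ground truth (shared, read-only)."""
    cfg = CohortConfig(n_patients=60, seed=7)
    patients, gt = generate_cohort(cfg, [horizon])
    return cfg, patients, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
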