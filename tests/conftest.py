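import numpy as np
import pytest

from osteospec.synthetic import CohortConfig, draw_morphometry, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default 48-sample cohort (spectra + truth, no volumes)."""
    cfg = CohortConfig(seed=1)
    ds, _, truth = generate_cohort(cfg, with_volumes=False)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_truth():
    """Ground-truth table only, default conditions."""
    cfg = CohortConfig(seed=7)
    return draw_morphometry(cfg, np.random.default_rng(7))
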