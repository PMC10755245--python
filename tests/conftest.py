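import numpy as np
import pytest

from smokebag import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort reused across test modules (seeded)."""
    cfg = SimConfig(n_subjects=800, n_snps=400, n_causal=30, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
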