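import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort_spec():
    """Tiny cohort used by pipeline-level tests (fast, fs scaled down)."""
    from vagdfa import synthetic

    return synthetic.CohortSpec(
        n_per_group=3,
        fs_hz=1000.0,
        n_cycles=10,
        cycle_s=1.0,
        profiles=synthetic.default_profiles(1000.0),
        seed=7,
    )
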