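import numpy as np
import pytest

from swayemd import SyntheticCohortSpec, generate_cohort, generate_trial


@pytest.fixture(scope="session")
def short_trial():
    """One synthetic fall-group trial at 20 s / 100 Hz (2000 samples)."""
    spec = SyntheticCohortSpec(duration=20.0, seed=7)
    return generate_trial(spec, "fall", 0)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 4 + 4 cohort of 10 s trials, decomposed lazily by tests."""
    spec = SyntheticCohortSpec(n_fall=4, n_nonfall=4, duration=10.0, seed=11)
    recs, meta = generate_cohort(spec)
    return spec, recs, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
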