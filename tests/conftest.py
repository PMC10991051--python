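import numpy as np
import pytest

from affectval.synthetic_cohort import CohortSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_spec(**overrides) -> CohortSpec:
    """A fast cohort: 6 participants, 2 stimuli/condition, short stimuli."""
    defaults = dict(
        n_participants=6,
        stimuli_per_condition={"negative": 2, "neutral": 2, "positive": 2},
        duration_mean=45.0, duration_sd=5.0,
        duration_min=35.0, duration_max=60.0,
        fraction_rated=1.0,
        rng_seed=42,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    bundle = simulate_cohort(small_spec())
    # small resampling sizes keep the session-wide fixtures fast
    bundle.config.n_boot = 500
    bundle.config.mcs_draws = 1000
    return bundle
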