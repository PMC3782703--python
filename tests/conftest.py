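import numpy as np
import pytest

from fcloo import SimParams, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """R=12, 3 sites x 8 subjects, planted effect: fast enough for oracles."""
    params = SimParams(
        R=12,
        n_sites=3,
        subjects_per_site=8,
        effect_fraction=0.1,
        effect_size=0.8,
        subject_noise_sd=0.15,
        seed=7,
    )
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the generator's default study conditions."""
    return simulate_cohort(SimParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
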