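import numpy as np
import pytest

from facepheno.synth import CohortConfig, GroupProfile, generate_cohort, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_profile():
    """A generic profile with activity on every feature type."""
    return GroupProfile(
        drift_rate=0.8, drift_span=1.2, intensity_base=0.1, intensity_peak=0.5,
        happy_bout_rate=1.5, happy_bout_len=10, ambiguity_temp=1.0,
        dynamics_style="smooth_ramp",
    )


@pytest.fixture
def small_session(small_profile):
    """One K=6, L=50 session with non-trivial values everywhere."""
    return generate_session(small_profile, K=6, L=50, seed=7,
                            subject_id="s007", group="TD")


@pytest.fixture
def tiny_cohort():
    """Twelve K=6, L=50 sessions (6 ASD / 6 TD) from the default profiles."""
    sessions, _ = generate_cohort(CohortConfig(n_asd=6, n_td=6, L=50, seed=3))
    return sessions
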