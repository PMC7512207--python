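import numpy as np
import pytest

from eegscreen.features import feature_table
from eegscreen.synthetic import CohortConfig, GroupProfile, generate_cohort


def small_weights(delta=0.10, theta=0.06, alpha=0.45, beta1=0.12, beta2=0.10,
                  gamma=0.04):
    w = dict(delta=delta, theta=theta, alpha=alpha, beta1=beta1, beta2=beta2,
             gamma=gamma)
    s = sum(w.values())
    w = {k: v / s for k, v in w.items()}
    w["gamma"] += 1.0 - sum(w.values())
    return w


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """3 subjects per group, cheap enough for repeated use."""
    return CohortConfig(n_subjects_per_group=3, trials_per_subject_mean=4,
                        trials_per_subject_sd=1, n_channels=2, rng_seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cohort_config):
    return generate_cohort(tiny_cohort_config)


@pytest.fixture(scope="session")
def small_feature_table():
    """Feature table of a small default-profile cohort (shared across tests)."""
    cfg = CohortConfig(n_subjects_per_group=4, trials_per_subject_mean=5,
                       trials_per_subject_sd=1, n_channels=2, rng_seed=7)
    return feature_table(generate_cohort(cfg))


@pytest.fixture(scope="session")
def pure_alpha_profile():
    """Noise-free profile whose only oscillator is a razor-thin 10 Hz alpha."""
    return GroupProfile("HC", 10.0,
                        dict(delta=0.0, theta=0.0, alpha=1.0, beta1=0.0,
                             beta2=0.0, gamma=0.0),
                        noise_fraction=0.0, alpha_bandwidth_hz=0.05)
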