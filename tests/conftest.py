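import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from betabursts.config import load_config
from betabursts.pipeline import compute_envelopes, gen_cohort_from_config

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_COHORT_OVERRIDES = {
    "synth": {
        "duration_s": 60.0,
        "groups": [
            {
                "label": "patient",
                "n_subjects": 3,
                "rate_mean": 106.0,
                "rate_sd": 8.0,
                "noise_exponent": 0.8,
            },
            {
                "label": "control",
                "n_subjects": 3,
                "rate_mean": 120.0,
                "rate_sd": 11.0,
                "noise_exponent": 0.65,
            },
        ],
    },
    "threshold": {"k_step": 0.5},
    "sweep": {"k_step": 1.0},
}


@pytest.fixture(scope="session")
def small_config():
    return load_config(overrides=SMALL_COHORT_OVERRIDES)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Six subjects, two sessions, 60-s records: fast but full-structure."""
    return gen_cohort_from_config(small_config, seed=7)


@pytest.fixture(scope="session")
def small_envelopes(small_cohort, small_config):
    envelopes, errors = compute_envelopes(small_cohort, small_config)
    assert not errors
    return envelopes


def gaussian_bump_envelope(
    fs=1000.0,
    duration_s=10.0,
    baseline=1.0,
    bumps=((5.0, 3.0, 0.030),),
):
    """Envelope of constant baseline plus Gaussian bumps (center_s, peak, sigma_s)."""
    from betabursts.datatypes import Envelope

    t = np.arange(int(duration_s * fs)) / fs
    mag = np.full(t.size, baseline)
    for center, peak, sigma in bumps:
        mag += (peak - baseline) * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return Envelope(mag, fs=fs, band=(13.0, 30.0))
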