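import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fnirs_deception as fd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


NOISELESS = dict(
    noise_cardiac=0.0, noise_respiratory=0.0, noise_drift=0.0, noise_white=0.0
)


@pytest.fixture(scope="session")
def noiseless_subject():
    """One synthetic subject with signal but no physiological noise."""
    cfg = fd.SyntheticConfig(**NOISELESS)
    rec, truth = fd.simulate_subject(cfg, seed=7, subject_id="S01")
    return cfg, rec, truth


@pytest.fixture(scope="session")
def default_subject():
    """One subject under the default (noisy) study conditions."""
    cfg = fd.SyntheticConfig()
    rec, truth = fd.simulate_subject(cfg, seed=3, subject_id="S01")
    return cfg, rec, truth


@pytest.fixture(scope="session")
def default_features(default_subject):
    """Question features of the default subject (full preprocessing chain)."""
    _, rec, truth = default_subject
    series = fd.preprocess_recording(rec)
    return fd.compute_question_features(series), truth


@pytest.fixture(scope="session")
def small_cohort():
    """Four default-condition subjects, preprocessed and epoched."""
    cfg = fd.SyntheticConfig(n_subjects=4)
    out = []
    for rec, truth in fd.simulate_cohort(cfg):
        qf = fd.compute_question_features(fd.preprocess_recording(rec))
        out.append((qf, truth))
    return cfg, out
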