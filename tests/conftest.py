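import numpy as np
import pytest

from capscore.features import extract_feature_matrix
from capscore.synth import SyntheticSpec, generate_background, generate_cohort, plant_a_phases


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def short_recording():
    """10-minute single-subject recording with planted A-phases."""
    spec = SyntheticSpec(n_subjects=1, duration=600.0, seed=7)
    bg = generate_background(spec.duration, spec.fs, spec.background_sigma,
                             seed=spec.seed, subject_id="S001")
    rec, labels, events = plant_a_phases(bg, spec, seed=spec.seed + 1)
    return rec, labels, events


@pytest.fixture(scope="session")
def short_features(short_recording):
    rec, labels, _ = short_recording
    return extract_feature_matrix(rec), labels


@pytest.fixture(scope="session")
def easy_cohort():
    """The 8-subject, 20-min/subject well-separated cohort (fixed seed)."""
    return generate_cohort(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def easy_cohort_features(easy_cohort):
    return [extract_feature_matrix(r) for r in easy_cohort.recordings]
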