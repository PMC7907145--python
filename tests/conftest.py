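import numpy as np
import pytest

from eegtopo.features import feature_frames
from eegtopo.montage_layout import SMALL_16_LABELS
from eegtopo.signal_prep import segment_trials, sliding_windows
from eegtopo.synth_eeg import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def extract_trial_features(cohort, feature_name="fuzzyen", max_trials=None):
    """(flat feature matrix, labels, subject ids); one row per trial."""
    rows, labels, subjects = [], [], []
    for rec in cohort:
        for trial in segment_trials(rec, 1.4, max_trials):
            frames = feature_frames(
                sliding_windows(trial), feature_name=feature_name, fs=rec.sampling_rate
            )
            rows.append(np.concatenate([f.values.ravel() for f in frames]))
            labels.append(rec.label)
            subjects.append(rec.subject_id)
    return np.array(rows), np.array(labels), np.array(subjects)


@pytest.fixture(scope="session")
def effect_cohort_config():
    return SynthConfig(
        n_subjects_per_class=6,
        trials_per_subject=6,
        channel_labels=SMALL_16_LABELS,
        complexity_effect=0.8,
        seed=11,
    )


@pytest.fixture(scope="session")
def effect_cohort(effect_cohort_config):
    return generate_cohort(effect_cohort_config)


@pytest.fixture(scope="session")
def effect_features(effect_cohort):
    return extract_trial_features(effect_cohort)


@pytest.fixture(scope="session")
def null_cohort():
    cfg = SynthConfig(
        n_subjects_per_class=6,
        trials_per_subject=6,
        channel_labels=SMALL_16_LABELS,
        complexity_effect=0.0,
        theta_power_effect=1.0,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_features(null_cohort):
    return extract_trial_features(null_cohort)
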