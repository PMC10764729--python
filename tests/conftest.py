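import numpy as np
import pytest

from pupilbayes.preprocess import SampleSeries, preprocess_study
from pupilbayes.synthetic import SimConfig, simulate_study


def make_series(
    pupil,
    valid=None,
    fs: float = 250.0,
    participant_id: str = "P001",
    gaze_x=None,
    gaze_y=None,
) -> SampleSeries:
    pupil = np.asarray(pupil, dtype=float)
    n = pupil.size
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return SampleSeries(
        participant_id=participant_id,
        time_s=np.arange(n) / fs,
        pupil=pupil,
        gaze_x_px=np.zeros(n) if gaze_x is None else np.asarray(gaze_x, float),
        gaze_y_px=np.zeros(n) if gaze_y is None else np.asarray(gaze_y, float),
        valid=np.asarray(valid, dtype=bool),
        sampling_rate_hz=fs,
    )


@pytest.fixture(scope="session")
def artifact_study():
    """Small cohort with planted blinks, whole-trial missing runs and
    gaze excursions on both sides of the 1-s rule."""
    cfg = SimConfig(
        n_participants=10,
        seed=123,
        blink_rate=4.0,
        gaze_excursion_prob=0.25,
        missing_trial_prob=0.12,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def artifact_pipeline(artifact_study):
    cleaned, reports, windows = preprocess_study(artifact_study.session_pairs())
    return cleaned, reports, windows


@pytest.fixture(scope="session")
def noisefree_study():
    """Deterministic signal: no sample noise, no drift, no blinks, no
    trial-to-trial slope jitter, no artifacts."""
    cfg = SimConfig(
        n_participants=4,
        seed=7,
        trial_noise_sd=0.0,
        drift_sd=0.0,
        blink_rate=0.0,
        gaze_excursion_prob=0.0,
        missing_trial_prob=0.0,
        reliability_target=1.0,
        true_rho=0.0,
    )
    return simulate_study(cfg)
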