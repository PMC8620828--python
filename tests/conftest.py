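import numpy as np
import pytest

from ecgpair import DegradationSpec, SessionConfig, generate_paired_session


@pytest.fixture
def clean_session():
    """Short clean paired session with zero lag, shared ground truth."""
    cfg = SessionConfig(duration_s=60.0, sync_times_s=(5.0, 55.0))
    return generate_paired_session(cfg, seed=123)


def make_session(duration_s=60.0, seed=0, lag=0.0, drift=0.0, snr_db=None,
                 saturation=(), mean_hr=75.0, sync_times=(5.0, 55.0),
                 smear_cutoff_hz=None, gain=1.0, sdnn_ms=50.0, sdsd_ms=30.0):
    """Session factory used across the suite."""
    cfg = SessionConfig(
        duration_s=duration_s,
        mean_hr=mean_hr,
        sdnn_ms=sdnn_ms,
        sdsd_ms=sdsd_ms,
        sync_times_s=sync_times,
        exp_degradation=DegradationSpec(
            snr_db=snr_db, lag_samples=lag, drift_samples_per_s=drift,
            saturation_episodes=list(saturation), smear_cutoff_hz=smear_cutoff_hz,
            gain=gain),
    )
    return generate_paired_session(cfg, seed=seed)


@pytest.fixture
def session_factory():
    return make_session
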