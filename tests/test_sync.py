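"""Acoustic sync: event detection, lag/drift estimation, alignment."""

import numpy as np
import pytest

from ecgpair import (Recording, align, detect_sync_events, estimate_lag)


def pulse_channel(duration_s, times_s, fs=1000.0, width_s=0.05, noise=0.005,
                  seed=0):
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    x = rng.normal(0.0, noise, n)
    for t in times_s:
        a = int(np.ceil(t * fs))
        x[a:a + int(width_s * fs)] += 1.0
    return Recording(samples=x, fs=fs, adc_range=(-2.0, 2.0), label="sync",
                     units="au")


class TestDetectEvents:
    def test_flat_zero_channel_yields_no_events(self):
        rec = Recording(samples=np.zeros(5000), fs=1000.0, label="sync", units="au")
        assert detect_sync_events(rec).size == 0

    def test_pulses_recovered_within_one_sample(self):
        truth = [10.0, 450.0, 890.0]
        rec = pulse_channel(900.0, truth)
        ev = detect_sync_events(rec)
        assert ev.size == 3
        assert np.max(np.abs(ev - np.asarray(truth))) <= 1.0 / rec.fs

    def test_close_pulses_merge_within_min_separation(self):
        rec = pulse_channel(10.0, [5.0, 5.05])
        ev = detect_sync_events(rec, min_separation=1.0)
        assert ev.size == 1

    def test_empty_recording_raises(self):
        rec = Recording(samples=np.zeros(10), fs=1000.0, label="s", units="au")
        with pytest.raises(ValueError):
            detect_sync_events(rec.copy_with(samples=np.array([])))


class TestEstimateLag:
    def test_identical_event_lists(self):
        ev = np.array([1.0, 5.0, 9.0])
        est = estimate_lag(ev, ev, fs=1000.0)
        assert est.lag == 0.0 and est.drift == 0.0 and est.residual == 0.0

    def test_constant_lag_three_events(self):
        trig = np.array([10.0, 450.0, 890.0])
        est = estimate_lag(trig, trig + 0.250, fs=1000.0)
        assert est.lag == pytest.approx(250.0, abs=1.0)
        assert est.drift == pytest.approx(0.0, abs=1e-9)

    def test_linear_drift_recovered(self):
        trig = np.array([10.0, 230.0, 450.0, 670.0, 890.0])
        drift = 0.5  # samples per second
        resp = trig + (100.0 + drift * trig) / 1000.0
        est = estimate_lag(trig, resp, fs=1000.0)
        assert abs(est.drift - drift) / drift < 0.10
        assert est.lag == pytest.approx(100.0, abs=1.0)

    def test_count_mismatch_of_one_tolerated(self):
        trig = np.array([10.0, 40.0, 70.0])
        resp = np.array([10.1, 40.1, 70.1, 95.0])  # spurious trailing event
        est = estimate_lag(trig, resp, fs=1000.0)
        assert est.lag == pytest.approx(100.0, abs=1.0)

    def test_count_mismatch_beyond_one_raises(self):
        with pytest.raises(ValueError, match="trigger"):
            estimate_lag(np.array([1.0]), np.array([1.0, 2.0, 3.0]), fs=1000.0)


class TestAlign:
    def test_zero_lag_is_identity_up_to_truncation(self, session_factory):
        s = session_factory(duration_s=20.0, sync_times=(2.0, 18.0))
        ev = detect_sync_events(s.sync_trigger)
        est = estimate_lag(ev, detect_sync_events(s.sync_response), s.fs)
        out = align(s, est)
        assert out.ref.n_samples == s.ref.n_samples
        assert np.allclose(out.exp.samples, s.exp.samples, atol=1e-9)

    def test_lag_250_aligns_peaks_to_reference_truth(self, session_factory):
        s = session_factory(duration_s=30.0, lag=250.0, sync_times=(2.0, 28.0))
        est = estimate_lag(detect_sync_events(s.sync_trigger),
                           detect_sync_events(s.sync_response), s.fs)
        out = align(s, est)
        from ecgpair import detect_rpeaks, fir_filter
        ann = detect_rpeaks(fir_filter(out.exp))
        gt = out.ground_truth.r_peaks_ref
        gt = gt[(gt > 300) & (gt < out.ref.n_samples - 300)]
        errs = np.min(np.abs(ann.r_peaks[:, None] - gt[None, :]), axis=0)
        assert np.max(errs) <= 1

    def test_full_length_lag_raises(self, session_factory):
        s = session_factory(duration_s=5.0, sync_times=(1.0, 4.0))
        est = estimate_lag(np.array([1.0]), np.array([1.0]), s.fs)
        est.lag = float(s.ref.n_samples)
        with pytest.raises(ValueError):
            align(s, est)


class TestRecoveryProperty:
    """Random lag/drift configurations are recovered to spec."""

    def test_recovery_over_seeded_configs(self, session_factory):
        rng = np.random.default_rng(2024)
        for i in range(5):  # wider sweep lives in the acceptance suite
            lag = float(rng.integers(-5000, 5000))
            drift = float(rng.uniform(0.2, 1.0))
            s = session_factory(duration_s=120.0, lag=lag, drift=drift,
                                sync_times=(5.0, 35.0, 65.0, 95.0, 115.0),
                                seed=300 + i)
            est = estimate_lag(detect_sync_events(s.sync_trigger),
                               detect_sync_events(s.sync_response), s.fs)
            assert abs(est.lag - lag) <= 1.0
            assert abs(est.drift - drift) / drift <= 0.10
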