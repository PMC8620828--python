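"""Synthetic-data generator: target recovery, determinism, degradation accounting."""

import numpy as np
import pytest

from ecgpair import (BeatTemplateParams, DegradationSpec, RRSeries, SessionConfig,
                     apply_degradation, generate_paired_session, generate_rr_series,
                     synthesize_ecg)


class TestGenerateRR:
    def test_zero_variability_gives_exact_intervals(self):
        rr = generate_rr_series(60.0, 0.0, 0.0, 10, seed=99)
        assert np.array_equal(rr.intervals, np.full(10, 1000.0))

    def test_sdnn_recovery_at_1000_beats(self):
        rr = generate_rr_series(75.0, 50.0, 30.0, 1000, seed=1)
        assert 45.0 <= np.std(rr.intervals, ddof=1) <= 55.0

    def test_determinism(self):
        a = generate_rr_series(75.0, 50.0, 30.0, 500, seed=7)
        b = generate_rr_series(75.0, 50.0, 30.0, 500, seed=7)
        assert np.array_equal(a.intervals, b.intervals)

    def test_target_recovery_converges(self):
        rr = generate_rr_series(70.0, 60.0, 35.0, 2000, seed=5)
        sdnn = np.std(rr.intervals, ddof=1)
        sdsd = np.std(np.diff(rr.intervals), ddof=1)
        hr = 60000.0 / np.mean(rr.intervals)
        assert abs(sdnn - 60.0) / 60.0 < 0.05
        assert abs(sdsd - 35.0) / 35.0 < 0.05
        assert abs(hr - 70.0) / 70.0 < 0.02

    @pytest.mark.parametrize("kwargs", [
        dict(mean_hr=75, sdnn_target=50, sdsd_target=30, n_beats=1),
        dict(mean_hr=300, sdnn_target=50, sdsd_target=30, n_beats=10),
        dict(mean_hr=75, sdnn_target=10, sdsd_target=25, n_beats=10),  # SDSD >= 2*SDNN
        dict(mean_hr=75, sdnn_target=-1, sdsd_target=0, n_beats=10),
    ])
    def test_invalid_inputs_raise(self, kwargs):
        with pytest.raises(ValueError):
            generate_rr_series(kwargs["mean_hr"], kwargs["sdnn_target"],
                               kwargs["sdsd_target"], kwargs["n_beats"], seed=0)


class TestSynthesizeECG:
    def test_metronomic_rr_places_peaks_exactly(self):
        rr = RRSeries(np.full(10, 1000.0))
        rec, r_idx = synthesize_ecg(rr, fs=1000.0)
        assert r_idx.size == 10
        assert np.all(np.diff(r_idx) == 1000)
        # the signal's local maximum sits at each recorded index
        for p in r_idx:
            w = rec.samples[p - 50:p + 51]
            assert np.argmax(w) == 50

    def test_r_amplitude_reached_within_wave_overlap(self):
        rr = RRSeries(np.full(5, 1000.0))
        rec, r_idx = synthesize_ecg(rr, fs=1000.0)
        for p in r_idx:
            assert rec.samples[p] == pytest.approx(1.0, rel=0.01)

    def test_empty_rr_raises(self):
        with pytest.raises(ValueError):
            synthesize_ecg(RRSeries(np.array([])), fs=1000.0)

    def test_low_fs_raises(self):
        with pytest.raises(ValueError):
            synthesize_ecg(RRSeries(np.full(3, 1000.0)), fs=50.0)


class TestApplyDegradation:
    def _rec(self, duration_s=30.0, seed=0):
        rr = generate_rr_series(75.0, 50.0, 30.0, 60, seed=seed)
        rec, _ = synthesize_ecg(rr, fs=1000.0, duration_s=duration_s)
        return rec

    def test_identity_spec_is_identity(self):
        rec = self._rec()
        out, mask = apply_degradation(rec, DegradationSpec(), seed=4)
        assert np.array_equal(out.samples, rec.samples)
        assert not mask.any()

    def test_mask_covers_exact_episode_duration(self):
        rec = self._rec()
        spec = DegradationSpec(saturation_episodes=[(5.0, 3.0), (20.0, 2.0)])
        _, mask = apply_degradation(rec, spec, seed=4)
        assert int(mask.sum()) == int(5.0 * rec.fs)
        runs = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        assert runs.tolist() == [5000, 8000, 20000, 22000]

    def test_saturated_samples_rail_at_upper_bound(self):
        rec = self._rec()
        spec = DegradationSpec(saturation_episodes=[(5.0, 3.0)])
        out, mask = apply_degradation(rec, spec, seed=4)
        assert np.all(out.samples[mask] == rec.adc_range[1])

    def test_snr_recovered_within_1db(self):
        rec = self._rec()
        out, _ = apply_degradation(rec, DegradationSpec(snr_db=10.0), seed=4)
        noise = out.samples - rec.samples
        snr = 10.0 * np.log10(np.mean(rec.samples**2) / np.mean(noise**2))
        assert abs(snr - 10.0) < 1.0

    def test_degradation_deterministic_given_seed(self):
        rec = self._rec()
        spec = DegradationSpec(snr_db=15.0, wander_amplitude_mv=0.2)
        a, _ = apply_degradation(rec, spec, seed=8)
        b, _ = apply_degradation(rec, spec, seed=8)
        assert np.array_equal(a.samples, b.samples)

    def test_overlapping_episodes_rejected(self):
        with pytest.raises(ValueError):
            DegradationSpec(saturation_episodes=[(5.0, 3.0), (6.0, 1.0)])


class TestGeneratePairedSession:
    def test_zero_lag_no_degradation_channels_identical(self):
        cfg = SessionConfig(duration_s=30.0, sync_times_s=(5.0, 25.0))
        s = generate_paired_session(cfg, seed=2)
        assert np.allclose(s.ref.samples, s.exp.samples, atol=1e-12)

    def test_sync_channel_cross_correlation_peaks_at_lag(self):
        cfg = SessionConfig(
            duration_s=30.0, sync_times_s=(5.0, 25.0), sync_noise_floor=0.0,
            exp_degradation=DegradationSpec(lag_samples=250))
        s = generate_paired_session(cfg, seed=2)
        trig = s.sync_trigger.samples
        resp = s.sync_response.samples
        # brute-force lag scan
        lags = np.arange(0, 600)
        score = [np.dot(resp[l:], trig[:trig.size - l]) for l in lags]
        assert lags[int(np.argmax(score))] == 250

    def test_fifteen_minute_session_layout(self):
        cfg = SessionConfig(duration_s=900.0, sync_times_s=(10.0, 450.0, 890.0))
        s = generate_paired_session(cfg, seed=3)
        assert all(c.n_samples == 900_000 for c in s.channels())
        assert len(s.channels()) == 4
        assert s.ground_truth.sync_times.size == 3

    def test_lag_exceeding_length_raises(self):
        cfg = SessionConfig(duration_s=10.0, sync_times_s=(5.0,),
                            exp_degradation=DegradationSpec(lag_samples=20000))
        with pytest.raises(ValueError):
            generate_paired_session(cfg, seed=0)

    def test_session_determinism(self):
        cfg = SessionConfig(duration_s=20.0, sync_times_s=(5.0, 15.0),
                            exp_degradation=DegradationSpec(snr_db=20.0))
        a = generate_paired_session(cfg, seed=5)
        b = generate_paired_session(cfg, seed=5)
        assert np.array_equal(a.exp.samples, b.exp.samples)
        assert np.array_equal(a.ground_truth.r_peaks_ref, b.ground_truth.r_peaks_ref)
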