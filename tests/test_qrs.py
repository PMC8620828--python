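"""R-peak detection, dual-device matching, and rhythm comparison."""

import numpy as np
import pytest

from ecgpair import (BeatAnnotation, MatchedBeats, Recording, compare_rhythm,
                     detect_rpeaks, fir_filter, flag_invalid, match_beats)


class TestDetectRPeaks:
    def test_flatline_yields_no_peaks(self):
        rec = Recording(samples=np.zeros(10000), fs=1000.0)
        assert len(detect_rpeaks(rec)) == 0

    def test_clean_60bpm_minute(self, session_factory):
        s = session_factory(duration_s=60.0, mean_hr=60.0, sdnn_ms=30.0,
                            sdsd_ms=20.0, seed=21)
        ann = detect_rpeaks(fir_filter(s.ref))
        gt = s.ground_truth.r_peaks_ref
        assert abs(len(ann) - len(gt)) <= 1
        errs = np.min(np.abs(ann.r_peaks[:, None] - gt[None, :]), axis=1)
        assert np.max(errs) <= 0.010 * s.fs  # within 10 ms

    def test_no_detections_inside_saturated_gap(self, session_factory):
        s = session_factory(duration_s=60.0, saturation=[(30.0, 5.0)],
                            snr_db=25.0, seed=22)
        mask = flag_invalid(s.exp)
        ann = detect_rpeaks(fir_filter(s.exp), invalid_mask=mask)
        in_gap = (ann.r_peaks > 30.0 * s.fs) & (ann.r_peaks < 35.0 * s.fs)
        assert not in_gap.any()
        # detection resumes within two beats after the gap
        after = ann.r_peaks[ann.r_peaks >= 35.0 * s.fs]
        gt_after = s.ground_truth.r_peaks_exp[
            s.ground_truth.r_peaks_exp >= 35.0 * s.fs]
        assert after.size > 0
        assert after[0] <= gt_after[2] if gt_after.size >= 3 else True

    def test_too_short_recording_raises(self):
        with pytest.raises(ValueError):
            detect_rpeaks(Recording(samples=np.zeros(10), fs=1000.0))


class TestMatchBeats:
    def test_identical_annotations_fully_paired(self):
        ann = BeatAnnotation(np.arange(0, 60000, 1000), fs=1000.0)
        m = match_beats(ann, ann)
        assert len(m.pairs) == len(ann)
        assert not m.unmatched_ref and not m.unmatched_exp

    def test_missing_every_20th_gives_95_percent(self):
        ref_peaks = np.arange(1000, 1001000, 1000)  # 1000 beats
        keep = np.ones(ref_peaks.size, dtype=bool)
        keep[19::20] = False
        ref = BeatAnnotation(ref_peaks, fs=1000.0)
        exp = BeatAnnotation(ref_peaks[keep], fs=1000.0)
        m = match_beats(ref, exp)
        qrs_pct = 100.0 * len(m.pairs) / len(ref)
        assert qrs_pct == pytest.approx(95.0)

    def test_shift_beyond_tolerance_pairs_nothing(self):
        ref = BeatAnnotation(np.arange(1000, 30000, 1000), fs=1000.0)
        exp = BeatAnnotation(ref.r_peaks + 101, fs=1000.0)
        m = match_beats(ref, exp, tolerance_ms=100.0)
        assert len(m.pairs) == 0

    def test_cardinality_symmetric_under_swap(self):
        rng = np.random.default_rng(5)
        a = np.unique(rng.integers(0, 100000, 80))
        b = np.unique(rng.integers(0, 100000, 90))
        ann_a = BeatAnnotation(a, fs=1000.0)
        ann_b = BeatAnnotation(b, fs=1000.0)
        m1 = match_beats(ann_a, ann_b)
        m2 = match_beats(ann_b, ann_a)
        assert {(i, j) for i, j in m1.pairs} == {(j, i) for i, j in m2.pairs}
        assert m1.unmatched_ref == m2.unmatched_exp
        assert m1.unmatched_exp == m2.unmatched_ref


class TestCompareRhythm:
    def test_identical_channels_null_delta(self):
        ann = BeatAnnotation(np.arange(1000, 61000, 1000), fs=1000.0)
        m = match_beats(ann, ann)
        r = compare_rhythm(m, ann, ann)
        assert r.delta_hr_mean == 0.0 and r.delta_hr_std == 0.0
        assert r.qrs_pct == 100.0
        assert r.hr_ref_mean == pytest.approx(60.0)

    def test_uniform_interval_lengthening_closed_form(self):
        # every experimental interval 10% longer -> dHR = HR_ref*(1 - 1/1.1)
        ref_peaks = np.arange(0, 50001, 1000)
        exp_peaks = np.round(ref_peaks * 1.1).astype(int)
        ref = BeatAnnotation(ref_peaks, fs=1000.0)
        exp = BeatAnnotation(exp_peaks, fs=1000.0)
        pairs = [(i, i) for i in range(len(ref_peaks))]
        m = MatchedBeats(pairs=pairs, unmatched_ref=[], unmatched_exp=[],
                         tolerance_ms=1e9)
        r = compare_rhythm(m, ref, exp)
        assert r.delta_hr_mean == pytest.approx(60.0 * (1 - 1 / 1.1), rel=1e-3)

    def test_single_pair_raises(self):
        ann = BeatAnnotation(np.array([1000, 2000]), fs=1000.0)
        m = MatchedBeats(pairs=[(0, 0)], unmatched_ref=[1], unmatched_exp=[1],
                         tolerance_ms=100.0)
        with pytest.raises(ValueError):
            compare_rhythm(m, ann, ann)

    def test_hr_only_over_consecutive_runs(self):
        # a hole in the middle must not create a bridged interval
        ref_peaks = np.arange(0, 10001, 1000)
        ref = BeatAnnotation(ref_peaks, fs=1000.0)
        exp = BeatAnnotation(np.delete(ref_peaks, 5), fs=1000.0)
        m = match_beats(ref, exp)
        r = compare_rhythm(m, ref, exp)
        # 11 ref beats, 10 matched, runs of 5+5 -> 8 intervals
        assert r.n_intervals == 8
        assert r.delta_hr_mean == 0.0


class TestDetectorGateSample:
    def test_sensitivity_and_ppv_on_clean_sessions(self, session_factory):
        """Spot check of the detector gate (full sweep in acceptance)."""
        tp = fn = fp = 0
        for i, hr in enumerate((50.0, 85.0, 120.0)):
            s = session_factory(duration_s=60.0, mean_hr=hr, snr_db=20.0,
                                seed=700 + i)
            ann = detect_rpeaks(fir_filter(s.exp))
            truth = BeatAnnotation(s.ground_truth.r_peaks_exp, s.fs)
            m = match_beats(truth, ann, tolerance_ms=50.0)
            tp += len(m.pairs)
            fn += len(m.unmatched_ref)
            fp += len(m.unmatched_exp)
        assert 100.0 * tp / (tp + fn) >= 99.5
        assert 100.0 * tp / (tp + fp) >= 99.5
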