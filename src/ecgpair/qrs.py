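"""Hamilton-style R-peak detection, dual-device beat matching, and rhythm comparison.

The detector follows the classic open-source description of Hamilton's
QRS detector: the filtered ECG is differentiated, rectified and
integrated over an 80 ms moving window; candidate peaks are accepted
against an adaptive threshold built from running 8-deep buffers of
recent QRS and noise peak amplitudes, with a 200 ms refractory period
and a missed-beat searchback when the current interval stretches past
1.5x the running RR average.  Accepted detections are then refined to
the local ECG maximum so the annotation marks the R wave itself.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy import stats

from .sigio import Recording

__all__ = ["BeatAnnotation", "MatchedBeats", "RhythmComparison",
           "detect_rpeaks", "match_beats", "compare_rhythm",
           "HamiltonParams"]


@dataclass
class BeatAnnotation:
    """R-peak sample indices on one channel."""

    r_peaks: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.r_peaks.size > 1 and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")

    def times_ms(self) -> np.ndarray:
        return self.r_peaks * 1000.0 / self.fs

    def __len__(self) -> int:
        return self.r_peaks.size


@dataclass
class MatchedBeats:
    """Greedy nearest-neighbour pairing of two annotations."""

    pairs: list[tuple[int, int]]      # (index into ref peaks, index into exp peaks)
    unmatched_ref: list[int]
    unmatched_exp: list[int]
    tolerance_ms: float


@dataclass
class RhythmComparison:
    """Matched-segment heart-rate comparison between the two channels."""

    hr_ref_mean: float
    hr_ref_std: float
    hr_exp_mean: float
    hr_exp_std: float
    delta_hr_mean: float
    delta_hr_std: float
    qrs_pct: float          # 100 * matched pairs / reference peaks
    spurious_pct: float     # 100 * unmatched experimental peaks / reference peaks
    p_value: float          # paired two-sided t-test on per-interval HR
    n_intervals: int


@dataclass
class HamiltonParams:
    """Tunables of the detection front-end and decision rule."""

    integration_window_s: float = 0.080
    refractory_s: float = 0.200
    buffer_len: int = 8
    threshold_coefficient: float = 0.3125
    searchback_factor: float = 1.5
    searchback_threshold_fraction: float = 0.5
    refine_window_s: float = 0.100


def _detection_function(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    d = np.abs(np.diff(x, prepend=x[0]))
    w = max(1, int(round(window_s * fs)))
    kernel = np.ones(w) / w
    return np.convolve(d, kernel, mode="same")


def detect_rpeaks(rec: Recording, invalid_mask: Optional[np.ndarray] = None,
                  params: Optional[HamiltonParams] = None) -> BeatAnnotation:
    """Detect R peaks on a (filtered) recording.

    ``invalid_mask`` marks samples to exclude from detection (saturated
    stretches); the mask is dilated by the integration window so clip
    edges cannot masquerade as beats.
    """
    p = params or HamiltonParams()
    fs = rec.fs
    x = rec.samples
    w = max(1, int(round(p.integration_window_s * fs)))
    if x.size <= w:
        raise ValueError("recording shorter than the integration window")

    y = _detection_function(x, fs, p.integration_window_s)
    x_refine = x
    if invalid_mask is not None:
        invalid_mask = np.asarray(invalid_mask, dtype=bool)
        if invalid_mask.size != x.size:
            raise ValueError("invalid_mask length must equal signal length")
        dil = np.convolve(invalid_mask.astype(float), np.ones(2 * w + 1), mode="same") > 0
        y = np.where(dil, 0.0, y)
        # keep refinement off the saturation rail and its filter transients
        x_refine = np.where(dil, -np.inf, x)

    refractory = int(round(p.refractory_s * fs))
    cand, _ = sps.find_peaks(y, distance=max(1, refractory))
    if cand.size == 0:
        return BeatAnnotation(np.array([], dtype=int), fs)

    # threshold state: running buffers of recent QRS / noise peak heights
    head = y[: int(min(y.size, 2 * fs))]
    qrs_buf: deque = deque([float(np.max(head))], maxlen=p.buffer_len)
    noise_buf: deque = deque([float(np.median(head))], maxlen=p.buffer_len)
    rr_buf: deque = deque(maxlen=p.buffer_len)

    def threshold() -> float:
        nq = float(np.mean(noise_buf))
        sq = float(np.mean(qrs_buf))
        return nq + p.threshold_coefficient * (sq - nq)

    accepted: list[int] = []
    rejected_since_last: list[int] = []

    for c in cand:
        th = threshold()
        is_beat = y[c] > th
        if is_beat and accepted and c - accepted[-1] < refractory:
            is_beat = False
        if is_beat:
            accepted.append(int(c))
            qrs_buf.append(float(y[c]))
            if len(accepted) > 1:
                rr_buf.append(accepted[-1] - accepted[-2])
            rejected_since_last = []
        else:
            noise_buf.append(float(y[c]))
            rejected_since_last.append(int(c))
            # searchback: interval overdue -> revisit rejected candidates
            if accepted and rr_buf:
                mean_rr = float(np.mean(rr_buf))
                if c - accepted[-1] > p.searchback_factor * mean_rr:
                    sb = [r for r in rejected_since_last
                          if r - accepted[-1] >= refractory
                          and y[r] > p.searchback_threshold_fraction * th]
                    if sb:
                        best = int(sb[int(np.argmax([y[r] for r in sb]))])
                        accepted.append(best)
                        qrs_buf.append(float(y[best]))
                        rr_buf.append(accepted[-1] - accepted[-2])
                        rejected_since_last = [r for r in rejected_since_last if r > best]

    # refine each detection to the local R maximum on the ECG itself
    half = int(round(p.refine_window_s * fs))
    refined = []
    for c in accepted:
        a, b = max(0, c - half), min(x.size, c + half + 1)
        window = x_refine[a:b]
        if not np.any(np.isfinite(window)):
            continue
        refined.append(a + int(np.argmax(window)))
    refined = np.unique(np.asarray(refined, dtype=int))
    # enforce the refractory period after refinement
    keep: list[int] = []
    for r in refined:
        if not keep or r - keep[-1] >= refractory:
            keep.append(int(r))
    return BeatAnnotation(np.asarray(keep, dtype=int), fs)


def match_beats(ref: BeatAnnotation, exp: BeatAnnotation,
                tolerance_ms: float = 100.0) -> MatchedBeats:
    """Greedy nearest-neighbour pairing of two annotations on a common clock.

    Candidate pairs within the tolerance are taken in order of
    increasing absolute time difference (ties broken toward the earlier
    reference peak, then the earlier experimental peak); each peak is
    used at most once.  Swapping the two annotations swaps the unmatched
    lists but leaves the pair set unchanged.
    """
    t_ref = ref.times_ms()
    t_exp = exp.times_ms()
    cands: list[tuple[float, float, float, int, int]] = []
    j0 = 0
    for i, tr in enumerate(t_ref):
        for j in range(np.searchsorted(t_exp, tr - tolerance_ms),
                       np.searchsorted(t_exp, tr + tolerance_ms, side="right")):
            dt = abs(t_exp[j] - tr)
            if dt <= tolerance_ms:
                cands.append((dt, tr, t_exp[j], i, j))
    cands.sort()
    used_ref: set[int] = set()
    used_exp: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in cands:
        if i in used_ref or j in used_exp:
            continue
        pairs.append((i, j))
        used_ref.add(i)
        used_exp.add(j)
    pairs.sort()
    return MatchedBeats(
        pairs=pairs,
        unmatched_ref=[i for i in range(len(t_ref)) if i not in used_ref],
        unmatched_exp=[j for j in range(len(t_exp)) if j not in used_exp],
        tolerance_ms=tolerance_ms,
    )


def compare_rhythm(matched: MatchedBeats, ref: BeatAnnotation,
                   exp: BeatAnnotation) -> RhythmComparison:
    """Matched-segment heart-rate comparison.

    Heart rate is computed only over *runs* of consecutive matched
    pairs — both the reference and the experimental peak of the next
    pair must be the immediate successors of the current pair's peaks —
    so unmatched gaps never contribute intervals.  Per interval,
    HR = 60000/NN(ms) and dHR = HR_ref - HR_exp; the p-value is a
    paired two-sided t-test over the per-interval heart rates.
    """
    if len(matched.pairs) < 2:
        raise ValueError("need at least 2 matched pairs to form an interval")
    t_ref = ref.times_ms()
    t_exp = exp.times_ms()
    hr_ref = []
    hr_exp = []
    for (i1, j1), (i2, j2) in zip(matched.pairs, matched.pairs[1:]):
        if i2 == i1 + 1 and j2 == j1 + 1:
            hr_ref.append(60000.0 / (t_ref[i2] - t_ref[i1]))
            hr_exp.append(60000.0 / (t_exp[j2] - t_exp[j1]))
    if not hr_ref:
        raise ValueError("no consecutive matched pairs: cannot form an interval")
    hr_ref = np.asarray(hr_ref)
    hr_exp = np.asarray(hr_exp)
    delta = hr_ref - hr_exp
    if hr_ref.size >= 2 and np.ptp(delta) > 0:
        p_value = float(stats.ttest_rel(hr_ref, hr_exp).pvalue)
    elif np.allclose(delta, 0.0):
        p_value = 1.0
    else:
        p_value = float("nan")
    ddof = 1 if hr_ref.size > 1 else 0
    return RhythmComparison(
        hr_ref_mean=float(np.mean(hr_ref)),
        hr_ref_std=float(np.std(hr_ref, ddof=ddof)),
        hr_exp_mean=float(np.mean(hr_exp)),
        hr_exp_std=float(np.std(hr_exp, ddof=ddof)),
        delta_hr_mean=float(np.mean(delta)),
        delta_hr_std=float(np.std(delta, ddof=ddof)),
        qrs_pct=100.0 * len(matched.pairs) / max(len(ref), 1),
        spurious_pct=100.0 * len(matched.unmatched_exp) / max(len(ref), 1),
        p_value=p_value,
        n_intervals=int(hr_ref.size),
    )
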