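"""Acoustic synchronization of independently clocked recordings.

The acquisition scheme fires a buzzer on the experimental device while a
microphone on the reference device picks the tone up, leaving matched
pulse events on both sync channels.  Event onsets are detected with a
robust adaptive threshold, paired in order, and the clock offset is
modeled as ``offset(t) = lag + drift * t`` (samples, with t in seconds
on the trigger clock).  Drift beyond linear is not identifiable on
15-minute sessions and is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sigio import PairedSession, Recording

__all__ = ["SyncEstimate", "detect_sync_events", "estimate_lag", "align"]


@dataclass
class SyncEstimate:
    """Pairing of sync events and the fitted clock model."""

    event_times_trigger: np.ndarray  # s
    event_times_response: np.ndarray  # s
    lag: float          # samples, offset at trigger time 0
    drift: float        # samples per second
    residual: float     # RMS deviation of per-event offsets from the fit, samples
    fs: float

    def offset_at(self, t: float | np.ndarray) -> np.ndarray:
        """Clock offset in samples at trigger time ``t`` seconds."""
        return self.lag + self.drift * np.asarray(t, dtype=float)


def detect_sync_events(rec: Recording, min_separation: float = 1.0,
                       k: float = 8.0, amplitude_fraction: float = 0.2,
                       ) -> np.ndarray:
    """Detect pulse onsets on a sync channel.

    Onsets are the first samples where the rectified signal exceeds an
    adaptive threshold of ``k`` normal-consistent MADs (1.4826 * MAD)
    above the median — with a floor of ``amplitude_fraction`` of the
    channel's rectified maximum, so a sensor's noise floor cannot fire
    events when loud pulses are present.  Onsets closer than
    ``min_separation`` seconds are merged (first onset kept).  Returns
    event times in seconds, sorted ascending; an empty array is a valid
    result.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    x = np.abs(rec.samples - np.median(rec.samples))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    threshold = max(med + k * 1.4826 * mad, amplitude_fraction * float(np.max(x)))
    above = x > threshold
    if not np.any(above):
        return np.array([])
    onsets = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    merged = [onsets[0]]
    min_gap = min_separation * rec.fs
    for o in onsets[1:]:
        if o - merged[-1] >= min_gap:
            merged.append(o)
    return np.asarray(merged, dtype=float) / rec.fs


def estimate_lag(trigger_events: np.ndarray, response_events: np.ndarray,
                 fs: float) -> SyncEstimate:
    """Estimate lag (and drift) from paired sync events.

    Events are paired in order.  A count mismatch of one is tolerated by
    dropping the end of the longer list that leaves the most consistent
    offsets; a larger mismatch raises.  With >= 3 events the offsets are
    fit by least squares against trigger time, giving the lag as the
    offset extrapolated to t=0 and the drift as the slope; with fewer
    events the lag is the median offset and drift is 0.
    """
    trig = np.sort(np.asarray(trigger_events, dtype=float))
    resp = np.sort(np.asarray(response_events, dtype=float))
    if trig.size == 0 or resp.size == 0:
        raise ValueError("need at least one event on each channel")
    if abs(trig.size - resp.size) > 1:
        raise ValueError(
            f"event count mismatch beyond tolerance: trigger has {trig.size}, "
            f"response has {resp.size}")
    if trig.size != resp.size:
        trig_is_longer = trig.size > resp.size
        longer = trig if trig_is_longer else resp
        shorter = resp if trig_is_longer else trig
        candidates = [longer[:-1], longer[1:]]
        spreads = [float(np.std(cand - shorter)) for cand in candidates]
        trimmed = candidates[int(np.argmin(spreads))]
        if trig_is_longer:
            trig = trimmed
        else:
            resp = trimmed

    offsets = (resp - trig) * fs  # samples
    if trig.size >= 3:
        drift, lag = np.polyfit(trig, offsets, 1)
        fit = lag + drift * trig
    else:
        lag = float(np.median(offsets))
        drift = 0.0
        fit = np.full_like(offsets, lag)
    residual = float(np.sqrt(np.mean((offsets - fit) ** 2)))
    return SyncEstimate(event_times_trigger=trig, event_times_response=resp,
                        lag=float(lag), drift=float(drift), residual=residual,
                        fs=float(fs))


def align(session: PairedSession, est: SyncEstimate) -> PairedSession:
    """Resample the experimental channels onto the reference clock.

    For each reference sample k the experimental channel is evaluated
    (linear interpolation) at sample position ``k + lag + drift*(k/fs)``.
    Only the overlap region — reference samples whose mapped position
    falls inside the experimental recording — is retained, on all
    channels, so the output session is shorter when the lag is nonzero.
    Ground truth, when present, is remapped onto the aligned clock.
    """
    fs = session.fs
    n_ref = session.ref.n_samples
    n_exp = session.exp.n_samples
    if abs(est.lag) >= n_exp:
        raise ValueError("lag exceeds recording length")

    k = np.arange(n_ref)
    pos = k + est.offset_at(k / fs)
    valid = (pos >= 0.0) & (pos <= n_exp - 1)
    if not np.any(valid):
        raise ValueError("empty overlap between reference and experimental channels")
    k0, k1 = int(np.flatnonzero(valid)[0]), int(np.flatnonzero(valid)[-1]) + 1

    def resample_exp(rec: Recording) -> Recording:
        samples = np.interp(pos[k0:k1], np.arange(rec.n_samples), rec.samples)
        return rec.copy_with(samples=samples)

    def truncate(rec: Recording) -> Recording:
        return rec.copy_with(samples=rec.samples[k0:k1])

    ref = truncate(session.ref)
    exp = resample_exp(session.exp)
    trig = truncate(session.sync_trigger) if session.sync_trigger is not None else None
    resp = resample_exp(session.sync_response) if session.sync_response is not None else None

    gt = session.ground_truth
    if gt is not None:
        # experimental peak at sample m maps to reference index solving
        # m = k + lag + drift*k/fs
        m = gt.r_peaks_exp.astype(float)
        k_exp = np.round((m - est.lag) / (1.0 + est.drift / fs)).astype(int) - k0
        k_exp = k_exp[(k_exp >= 0) & (k_exp < k1 - k0)]
        ref_peaks = gt.r_peaks_ref - k0
        ref_peaks = ref_peaks[(ref_peaks >= 0) & (ref_peaks < k1 - k0)]
        mask_exp_idx = np.clip(np.round(pos[k0:k1]).astype(int), 0, n_exp - 1)
        gt = replace(gt,
                     r_peaks_ref=ref_peaks,
                     r_peaks_exp=k_exp,
                     invalid_mask_ref=gt.invalid_mask_ref[k0:k1],
                     invalid_mask_exp=gt.invalid_mask_exp[mask_exp_idx])

    meta = dict(session.meta)
    meta["alignment"] = {"lag": est.lag, "drift": est.drift,
                         "residual": est.residual, "start_index": k0,
                         "stop_index": k1}
    return PairedSession(ref=ref, exp=exp, sync_trigger=trig, sync_response=resp,
                         ground_truth=gt, meta=meta)
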