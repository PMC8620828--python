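"""Heartbeat waveform extraction, outlier rejection, and similarity scoring.

Beats are windowed around each R peak, baseline-corrected, screened for
outliers against a median template, and matched reference/experimental
beats are scored point by point with Pearson's correlation coefficient
and a normalized RMS error (percent of the reference beat's
peak-to-peak range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qrs import BeatAnnotation, MatchedBeats
from .sigio import Recording

__all__ = ["BeatMatrix", "MorphologyReport", "extract_beats",
           "reject_outliers", "compare_morphology"]


@dataclass
class BeatMatrix:
    """Equal-length beat waveforms, one row per retained R peak.

    ``ann_indices`` maps each row back to the position of its peak in
    the source annotation (edge beats whose window does not fit inside
    the recording are dropped).  ``valid_mask`` marks beats that have
    survived outlier screening.
    """

    beats: np.ndarray            # (n_beats, n_samples)
    window_ms: tuple[float, float]   # (pre, post) relative to R; pre is negative
    fs: float
    ann_indices: np.ndarray      # positions in the source annotation
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_edge_dropped: int = 0

    def __post_init__(self) -> None:
        self.beats = np.atleast_2d(np.asarray(self.beats, dtype=float))
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.beats.shape[0], dtype=bool)
        self.ann_indices = np.asarray(self.ann_indices, dtype=int)

    @property
    def n_beats(self) -> int:
        return self.beats.shape[0]


@dataclass
class MorphologyReport:
    pcc: np.ndarray          # per scored pair, [-1, 1]
    nrmse: np.ndarray        # per scored pair, percent of reference range
    pcc_mean: float
    pcc_std: float
    nrmse_mean: float
    nrmse_std: float
    n_scored: int
    n_skipped: int           # pairs skipped (invalid beat or zero variance)


def extract_beats(rec: Recording, ann: BeatAnnotation,
                  window_ms: tuple[float, float] = (-200.0, 400.0),
                  baseline_ms: float = 40.0) -> BeatMatrix:
    """Cut a fixed window around each R peak.

    The default (-200, +400) ms window covers P-QRS-T at resting heart
    rates.  Each beat's baseline — the mean of its first ``baseline_ms``
    — is subtracted.  Beats whose window spills outside the recording
    are dropped (counted in ``n_edge_dropped``).
    """
    if len(ann) == 0:
        raise ValueError("empty annotation")
    pre, post = window_ms
    if not pre < 0 < post:
        raise ValueError("window must straddle the R peak (pre < 0 < post)")
    fs = rec.fs
    a_off = int(round(pre / 1000.0 * fs))
    b_off = int(round(post / 1000.0 * fs))
    nb = int(round(baseline_ms / 1000.0 * fs))
    rows = []
    kept = []
    for k, p in enumerate(ann.r_peaks):
        a, b = p + a_off, p + b_off
        if a < 0 or b >= rec.n_samples:
            continue
        beat = rec.samples[a:b + 1].astype(float)
        beat = beat - np.mean(beat[:max(nb, 1)])
        rows.append(beat)
        kept.append(k)
    if not rows:
        raise ValueError("no beats fit fully inside the recording")
    return BeatMatrix(beats=np.vstack(rows), window_ms=window_ms, fs=fs,
                      ann_indices=np.asarray(kept),
                      n_edge_dropped=len(ann) - len(rows))


def reject_outliers(bm: BeatMatrix, cosine_threshold: float = 0.8,
                    amplitude_band: tuple[float, float] = (0.5, 2.0),
                    ) -> BeatMatrix:
    """Flag outlier beats against a median template (two-pass).

    A beat is an outlier when its cosine similarity with the median
    template falls below ``cosine_threshold`` OR its peak-to-peak
    amplitude lies outside ``amplitude_band`` times the median
    peak-to-peak.  The template is recomputed from survivors once and
    the screen re-applied.  Raises if every beat is rejected.
    """
    if bm.n_beats < 3:
        raise ValueError("need at least 3 beats for outlier screening")

    def screen(valid: np.ndarray) -> np.ndarray:
        template = np.median(bm.beats[valid], axis=0)
        tnorm = np.linalg.norm(template)
        ptps = np.ptp(bm.beats, axis=1)
        med_ptp = float(np.median(ptps[valid]))
        ok = np.empty(bm.n_beats, dtype=bool)
        for i, beat in enumerate(bm.beats):
            bnorm = np.linalg.norm(beat)
            cos = (float(beat @ template) / (bnorm * tnorm)
                   if bnorm > 0 and tnorm > 0 else 0.0)
            amp_ok = (amplitude_band[0] * med_ptp <= ptps[i]
                      <= amplitude_band[1] * med_ptp)
            ok[i] = (cos >= cosine_threshold) and amp_ok
        return ok

    valid = screen(np.ones(bm.n_beats, dtype=bool))
    if np.any(valid):
        valid = screen(valid)
    if not np.any(valid):
        raise ValueError("all beats rejected as outliers; review thresholds "
                         "or signal quality")
    return BeatMatrix(beats=bm.beats, window_ms=bm.window_ms, fs=bm.fs,
                      ann_indices=bm.ann_indices, valid_mask=valid,
                      n_edge_dropped=bm.n_edge_dropped)


def compare_morphology(ref_beats: BeatMatrix, exp_beats: BeatMatrix,
                       matched: MatchedBeats) -> MorphologyReport:
    """Score matched beat pairs point by point.

    Only pairs whose reference *and* experimental beats exist and are
    valid are scored.  Per pair, PCC is the Pearson correlation of the
    two amplitude vectors and NRMSE = 100 * RMS(ref - exp) / ptp(ref).
    Zero-variance beats (PCC undefined) are skipped and counted.
    """
    if ref_beats.beats.shape[1] != exp_beats.beats.shape[1]:
        raise ValueError("beat matrices must share the extraction window")
    if ref_beats.fs != exp_beats.fs:
        raise ValueError("beat matrices must share the sampling rate")
    ref_row = {int(k): r for r, k in enumerate(ref_beats.ann_indices)}
    exp_row = {int(k): r for r, k in enumerate(exp_beats.ann_indices)}

    pccs, nrmses = [], []
    skipped = 0
    for i, j in matched.pairs:
        ri, rj = ref_row.get(i), exp_row.get(j)
        if ri is None or rj is None:
            skipped += 1
            continue
        if not (ref_beats.valid_mask[ri] and exp_beats.valid_mask[rj]):
            skipped += 1
            continue
        u = ref_beats.beats[ri]
        v = exp_beats.beats[rj]
        if np.ptp(u) == 0 or np.ptp(v) == 0:
            skipped += 1
            continue
        uc, vc = u - u.mean(), v - v.mean()
        pccs.append(float(uc @ vc / (np.linalg.norm(uc) * np.linalg.norm(vc))))
        nrmses.append(100.0 * float(np.sqrt(np.mean((u - v) ** 2))) / float(np.ptp(u)))
    if not pccs:
        raise ValueError("no valid matched pairs to score")
    pccs = np.asarray(pccs)
    nrmses = np.asarray(nrmses)
    ddof = 1 if pccs.size > 1 else 0
    return MorphologyReport(
        pcc=pccs, nrmse=nrmses,
        pcc_mean=float(np.mean(pccs)), pcc_std=float(np.std(pccs, ddof=ddof)),
        nrmse_mean=float(np.mean(nrmses)), nrmse_std=float(np.std(nrmses, ddof=ddof)),
        n_scored=int(pccs.size), n_skipped=skipped,
    )
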