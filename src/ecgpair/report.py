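"""Skin-electrode impedance, pipeline orchestration, and session reporting.

``run_pipeline`` executes the full validation chain on a stored paired
session — synchronize, preprocess, detect and match beats, then HRV and
morphology in parallel — and aggregates everything into a
:class:`SessionReport`.  A failure inside one analysis stage marks that
stage as skipped (with the reason) rather than aborting the rest, since
a saturated channel should still yield its quality statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from . import __version__
from .hrv import DFAResult, PoincareSummary, dfa, hrv_record, nn_intervals, poincare
from .morphology import MorphologyReport, compare_morphology, extract_beats, reject_outliers
from .preprocess import QualityReport, compute_sde, fir_filter, flag_invalid
from .qrs import BeatAnnotation, RhythmComparison, compare_rhythm, detect_rpeaks, match_beats
from .sigio import PairedSession, read_session
from .sync import detect_sync_events, estimate_lag, align

__all__ = ["ImpedanceMeasurement", "PipelineConfig", "SessionReport",
           "compute_impedance", "run_pipeline", "report_to_json",
           "render_tables"]


@dataclass
class ImpedanceMeasurement:
    """Skin-electrode impedance from the voltage-divider bench setup.

    With a known series resistor R and the peak amplitudes VA (across
    the reference resistor) and VB (across the skin-electrode
    interface) read off the oscilloscope, the impedance magnitude is
    Z = R * VA / VB.  Frequency is carried as metadata only.
    """

    R: float            # kOhm
    VA: float           # V
    VB: float           # V
    frequency: float    # Hz
    Z: float            # kOhm


def compute_impedance(R: float, VA: float, VB: float,
                      frequency: float = float("nan")) -> ImpedanceMeasurement:
    """Impedance magnitude Z = R * VA / VB (kOhm when R is in kOhm)."""
    if R <= 0:
        raise ValueError("reference resistance must be positive")
    if VB <= 0:
        raise ValueError("VB must be positive")
    return ImpedanceMeasurement(R=R, VA=VA, VB=VB, frequency=frequency,
                                Z=R * VA / VB)


@dataclass
class PipelineConfig:
    """Tunables of the full validation pipeline."""

    filter_band: tuple[float, float] = (3.0, 45.0)
    filter_order: Optional[int] = None       # None -> scales with fs
    match_tolerance_ms: float = 100.0
    beat_window_ms: tuple[float, float] = (-200.0, 400.0)
    outlier_cosine_threshold: float = 0.8
    dfa_short_range: tuple[int, int] = (4, 16)
    dfa_long_range: tuple[int, int] = (16, 64)
    sync_min_separation_s: float = 1.0
    min_beats_for_dfa: int = 256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StageResult:
    """Either a stage's payload or an explicit skip record."""

    ok: bool
    payload: Any = None
    skip_reason: Optional[str] = None

    @classmethod
    def skipped(cls, reason: str) -> "StageResult":
        return cls(ok=False, skip_reason=reason)


@dataclass
class SessionReport:
    quality: StageResult
    sync: StageResult
    rhythm: StageResult
    hrv_ref: StageResult
    hrv_exp: StageResult
    morphology: StageResult
    provenance: dict = field(default_factory=dict)


def _attempt(fn, stage: str) -> StageResult:
    try:
        return StageResult(ok=True, payload=fn())
    except (ValueError, RuntimeError) as exc:
        return StageResult.skipped(f"{stage}: {exc}")


def run_pipeline(session_path, config: Optional[PipelineConfig] = None,
                 ) -> SessionReport:
    """Run the full validation pipeline on a stored session.

    Stage order: sync -> preprocess -> QRS detection/matching ->
    (HRV, morphology).  Each stage either contributes results or an
    explicit skip record with its reason.
    """
    cfg = config or PipelineConfig()
    session = read_session(session_path) if not isinstance(session_path, PairedSession) \
        else session_path
    return run_pipeline_on(session, cfg)


def run_pipeline_on(session: PairedSession,
                    cfg: Optional[PipelineConfig] = None) -> SessionReport:
    """Same as :func:`run_pipeline` but on an in-memory session."""
    cfg = cfg or PipelineConfig()
    fs = session.fs

    # --- synchronization -------------------------------------------------
    def do_sync():
        if session.sync_trigger is None or session.sync_response is None:
            raise ValueError("sync channels absent")
        trig = detect_sync_events(session.sync_trigger, cfg.sync_min_separation_s)
        resp = detect_sync_events(session.sync_response, cfg.sync_min_separation_s)
        est = estimate_lag(trig, resp, fs)
        return est

    sync_res = _attempt(do_sync, "sync")
    if sync_res.ok:
        try:
            work = align(session, sync_res.payload)
        except ValueError as exc:
            sync_res = StageResult.skipped(f"align: {exc}")
            work = session
    else:
        work = session

    # --- preprocessing / quality ----------------------------------------
    invalid_exp = flag_invalid(work.exp)
    invalid_ref = flag_invalid(work.ref)
    quality = _attempt(lambda: compute_sde(invalid_exp, fs), "quality")

    filt_ref = fir_filter(work.ref, cfg.filter_band, cfg.filter_order)
    filt_exp = fir_filter(work.exp, cfg.filter_band, cfg.filter_order)

    # --- beat detection and matching -------------------------------------
    def do_detect(rec, mask):
        return detect_rpeaks(rec, invalid_mask=mask)

    ann_ref_res = _attempt(lambda: do_detect(filt_ref, invalid_ref), "detect ref")
    ann_exp_res = _attempt(lambda: do_detect(filt_exp, invalid_exp), "detect exp")

    rhythm = StageResult.skipped("rhythm: detection unavailable")
    morph = StageResult.skipped("morphology: detection unavailable")
    matched = None
    if ann_ref_res.ok and ann_exp_res.ok:
        ann_ref: BeatAnnotation = ann_ref_res.payload
        ann_exp: BeatAnnotation = ann_exp_res.payload
        matched = match_beats(ann_ref, ann_exp, cfg.match_tolerance_ms)
        rhythm = _attempt(lambda: compare_rhythm(matched, ann_ref, ann_exp), "rhythm")

        def do_morph():
            rb = reject_outliers(extract_beats(filt_ref, ann_ref, cfg.beat_window_ms),
                                 cfg.outlier_cosine_threshold)
            eb = reject_outliers(extract_beats(filt_exp, ann_exp, cfg.beat_window_ms),
                                 cfg.outlier_cosine_threshold)
            return compare_morphology(rb, eb, matched)

        morph = _attempt(do_morph, "morphology")

    # --- HRV per channel --------------------------------------------------
    def do_hrv(ann_res: StageResult):
        if not ann_res.ok:
            raise ValueError("detection unavailable")
        nn = nn_intervals(ann_res.payload)
        pc = poincare(nn)
        df = None
        if len(nn) >= cfg.min_beats_for_dfa:
            df = dfa(nn, cfg.dfa_short_range, cfg.dfa_long_range)
        return {"poincare": pc, "dfa": df, "record": hrv_record(pc, df)}

    hrv_ref = _attempt(lambda: do_hrv(ann_ref_res), "hrv ref")
    hrv_exp = _attempt(lambda: do_hrv(ann_exp_res), "hrv exp")

    provenance = {
        "config_hash": cfg.hash(),
        "config": cfg.to_dict(),
        "seed": session.meta.get("seed"),
        "software_version": __version__,
    }
    return SessionReport(quality=quality, sync=sync_res, rhythm=rhythm,
                         hrv_ref=hrv_ref, hrv_exp=hrv_exp, morphology=morph,
                         provenance=provenance)


def _jsonify(obj):
    if isinstance(obj, (PoincareSummary, QualityReport, RhythmComparison,
                        MorphologyReport, ImpedanceMeasurement)):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, DFAResult):
        d = dataclasses.asdict(obj)
        return _jsonify(d)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def report_to_json(report: SessionReport) -> str:
    """Serialize a report deterministically (sorted keys, no timestamps)."""

    def stage(sr: StageResult) -> dict:
        if not sr.ok:
            return {"skipped": True, "reason": sr.skip_reason}
        return {"skipped": False, "result": _jsonify(sr.payload)}

    doc = {
        "quality": stage(report.quality),
        "sync": stage(report.sync),
        "rhythm": stage(report.rhythm),
        "hrv_ref": stage(report.hrv_ref),
        "hrv_exp": stage(report.hrv_exp),
        "morphology": stage(report.morphology),
        "provenance": _jsonify(report.provenance),
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def render_tables(report: SessionReport) -> str:
    """Render the report as text tables mirroring the usual layouts."""
    lines: list[str] = []

    lines.append("== Rhythm comparison ==")
    if report.rhythm.ok and report.quality.ok:
        r: RhythmComparison = report.rhythm.payload
        q: QualityReport = report.quality.payload
        lines.append(f"{'QRS (%)':>12} {'HR (BPM)':>16} {'dHR (BPM)':>16} "
                     f"{'SDE (%)':>9} {'p-value':>9}")
        lines.append(f"{r.qrs_pct:12.2f} {r.hr_exp_mean:8.2f}±{r.hr_exp_std:<7.2f} "
                     f"{r.delta_hr_mean:8.3f}±{r.delta_hr_std:<7.3f} "
                     f"{q.sde_loss:9.2f} {r.p_value:9.3f}")
    else:
        reason = report.rhythm.skip_reason or report.quality.skip_reason
        lines.append(f"  skipped: {reason}")

    lines.append("")
    lines.append("== HRV (Poincaré / DFA) ==")
    lines.append(f"{'channel':>8} {'SD1 (ms)':>10} {'SD2 (ms)':>10} "
                 f"{'S (ms2)':>12} {'SD1/SD2':>8} {'a1':>6} {'a2':>6}")
    for name, st in (("REF", report.hrv_ref), ("EXP", report.hrv_exp)):
        if st.ok:
            pc: PoincareSummary = st.payload["poincare"]
            df = st.payload["dfa"]
            a1 = f"{df.alpha1:6.2f}" if df else "   n/a"
            a2 = f"{df.alpha2:6.2f}" if df else "   n/a"
            lines.append(f"{name:>8} {pc.SD1:10.1f} {pc.SD2:10.1f} "
                         f"{pc.S_area:12.1f} {pc.SD_ratio:8.2f} {a1} {a2}")
        else:
            lines.append(f"{name:>8}   skipped: {st.skip_reason}")

    lines.append("")
    lines.append("== Morphology ==")
    if report.morphology.ok:
        m: MorphologyReport = report.morphology.payload
        lines.append(f"PCC   = {m.pcc_mean:.3f} ± {m.pcc_std:.3f}  "
                     f"NRMSE = {m.nrmse_mean:.2f} ± {m.nrmse_std:.2f} %  "
                     f"(n={m.n_scored}, skipped={m.n_skipped})")
    else:
        lines.append(f"  skipped: {report.morphology.skip_reason}")
    return "\n".join(lines) + "\n"
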