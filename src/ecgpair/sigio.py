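"""Core data model and plain-text session I/O.

A *session* is a set of simultaneously recorded channels: the reference
ECG (gold standard), the experimental ECG (unobtrusive device), and two
acoustic synchronization channels — the buzzer drive on the experimental
device's clock reference ("O1") and the microphone response captured by
the reference device ("MIC").  Each channel is stored as a two-column
comma-separated text file (time in seconds, amplitude) next to a YAML
metadata sidecar, so that fixtures stay diffable and device-agnostic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "Recording",
    "GroundTruth",
    "PairedSession",
    "SessionFormatError",
    "write_session",
    "read_session",
]

METADATA_FILE = "metadata.yaml"
GROUND_TRUTH_FILE = "ground_truth.json"
# Amplitudes are written with 12 significant digits so a write/read
# round trip is lossless to well below 1e-9 mV.
_AMP_FMT = "%.12g"
_TIME_FMT = "%.9f"


class SessionFormatError(ValueError):
    """Raised when on-disk session data violates the documented dialect."""


@dataclass
class Recording:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples : ndarray
        Amplitudes, one per sample.  Millivolts unless ``units`` says
        otherwise.
    fs : float
        Sampling rate in Hz.
    adc_range : (float, float)
        Lower and upper bound of the acquisition range, in the same
        units as ``samples``.  Saturation railing happens at these
        bounds.
    label : str
        Channel name, unique within a session.
    units : str
        Amplitude units; ``"mV"`` for ECG channels, ``"au"`` for the
        acoustic sync channels.
    """

    samples: np.ndarray
    fs: float
    adc_range: tuple[float, float] = (-5.0, 5.0)
    label: str = "ecg"
    units: str = "mV"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        lo, hi = self.adc_range
        if not lo < hi:
            raise ValueError(f"adc_range must satisfy min < max, got {self.adc_range}")
        self.adc_range = (float(lo), float(hi))
        self.fs = float(self.fs)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def copy_with(self, **changes) -> "Recording":
        return replace(self, **changes)


@dataclass
class GroundTruth:
    """Known truth carried alongside synthetic sessions.

    ``lag`` and ``drift`` describe the experimental device's clock
    relative to the reference clock: an event at reference time ``t``
    (seconds) appears on the experimental channel at sample
    ``t*fs + lag + drift*t``.
    """

    r_peaks_ref: np.ndarray
    r_peaks_exp: np.ndarray
    invalid_mask_ref: np.ndarray
    invalid_mask_exp: np.ndarray
    lag: float = 0.0
    drift: float = 0.0
    sync_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.r_peaks_ref = np.asarray(self.r_peaks_ref, dtype=int)
        self.r_peaks_exp = np.asarray(self.r_peaks_exp, dtype=int)
        self.invalid_mask_ref = np.asarray(self.invalid_mask_ref, dtype=bool)
        self.invalid_mask_exp = np.asarray(self.invalid_mask_exp, dtype=bool)
        self.sync_times = np.asarray(self.sync_times, dtype=float)
        for name, peaks in (("r_peaks_ref", self.r_peaks_ref),
                            ("r_peaks_exp", self.r_peaks_exp)):
            if peaks.size > 1 and np.any(np.diff(peaks) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "r_peaks_ref": self.r_peaks_ref.tolist(),
            "r_peaks_exp": self.r_peaks_exp.tolist(),
            "invalid_mask_ref": _runs_from_mask(self.invalid_mask_ref),
            "invalid_mask_exp": _runs_from_mask(self.invalid_mask_exp),
            "mask_len_ref": int(self.invalid_mask_ref.size),
            "mask_len_exp": int(self.invalid_mask_exp.size),
            "lag": float(self.lag),
            "drift": float(self.drift),
            "sync_times": self.sync_times.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            r_peaks_ref=np.asarray(d["r_peaks_ref"], dtype=int),
            r_peaks_exp=np.asarray(d["r_peaks_exp"], dtype=int),
            invalid_mask_ref=_mask_from_runs(d["invalid_mask_ref"], d["mask_len_ref"]),
            invalid_mask_exp=_mask_from_runs(d["invalid_mask_exp"], d["mask_len_exp"]),
            lag=float(d["lag"]),
            drift=float(d["drift"]),
            sync_times=np.asarray(d["sync_times"], dtype=float),
        )


def _runs_from_mask(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask as [start, stop) index pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [[int(a), int(b)] for a, b in zip(starts, stops)]


def _mask_from_runs(runs: list[list[int]], length: int) -> np.ndarray:
    mask = np.zeros(int(length), dtype=bool)
    for a, b in runs:
        mask[a:b] = True
    return mask


@dataclass
class PairedSession:
    """Reference + experimental recordings with their sync channels."""

    ref: Recording
    exp: Recording
    sync_trigger: Optional[Recording] = None   # buzzer drive, "O1"
    sync_response: Optional[Recording] = None  # microphone, "MIC"
    ground_truth: Optional[GroundTruth] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        recs = self.channels()
        fss = {r.fs for r in recs}
        if len(fss) != 1:
            raise ValueError(f"all channels must share one sampling rate, got {sorted(fss)}")
        labels = [r.label for r in recs]
        if len(set(labels)) != len(labels):
            raise ValueError(f"channel labels must be unique, got {labels}")

    @property
    def fs(self) -> float:
        return self.ref.fs

    def channels(self) -> list[Recording]:
        return [r for r in (self.ref, self.exp, self.sync_trigger, self.sync_response)
                if r is not None]


def write_session(session: PairedSession, path: str | os.PathLike) -> Path:
    """Write a session as one CSV per channel plus a metadata sidecar.

    Round-trips losslessly with :func:`read_session` to < 1e-9 in
    amplitude.  Missing sync channels are recorded as explicit ``null``
    entries in the sidecar rather than silently omitted.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    channel_meta: dict[str, Optional[dict]] = {}
    slots = {
        "ref": session.ref,
        "exp": session.exp,
        "sync_trigger": session.sync_trigger,
        "sync_response": session.sync_response,
    }
    for slot, rec in slots.items():
        if rec is None:
            channel_meta[slot] = None
            continue
        fname = f"{slot}.csv"
        t = rec.times()
        with open(path / fname, "w") as fh:
            fh.write(f"# see {METADATA_FILE}\n")
            fh.write("time_s,amplitude\n")
            for ti, xi in zip(t, rec.samples):
                fh.write(f"{_TIME_FMT % ti},{_AMP_FMT % xi}\n")
        channel_meta[slot] = {
            "file": fname,
            "label": rec.label,
            "units": rec.units,
            "adc_range": [rec.adc_range[0], rec.adc_range[1]],
        }

    meta = {
        "format": "ecgpair-session/1",
        "fs": session.fs,
        "channels": channel_meta,
        "meta": session.meta,
    }
    with open(path / METADATA_FILE, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    if session.ground_truth is not None:
        with open(path / GROUND_TRUTH_FILE, "w") as fh:
            json.dump(session.ground_truth.to_dict(), fh)
    return path


def _read_channel(path: Path, fname: str, fs: float, cm: dict) -> Recording:
    fpath = path / fname
    header = None
    t_list: list[float] = []
    x_list: list[float] = []
    with open(fpath) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if header is None:
                header = s
                continue
            parts = s.split(",")
            if len(parts) != 2:
                raise SessionFormatError(
                    f"{fname}: expected 2 columns at line {lineno}, got {len(parts)}")
            try:
                t_list.append(float(parts[0]))
                x_list.append(float(parts[1]))
            except ValueError as exc:
                raise SessionFormatError(
                    f"{fname}: malformed value at line {lineno}") from exc
    if header is None or header.replace(" ", "") != "time_s,amplitude":
        raise SessionFormatError(f"{fname}: missing or unexpected header line")
    if not t_list:
        raise SessionFormatError(f"{fname}: no data rows")
    t = np.asarray(t_list, dtype=float)
    x = np.asarray(x_list, dtype=float)
    bad = np.flatnonzero(~(np.isfinite(t) & np.isfinite(x)))
    if bad.size:
        raise SessionFormatError(f"{fname}: non-finite value at data row {int(bad[0])}")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise SessionFormatError(f"{fname}: non-monotonic time column at data row {row}")
        step = 1.0 / fs
        if np.max(np.abs(dt - step)) > 1e-3 * step:
            raise SessionFormatError(
                f"{fname}: time step inconsistent with declared fs={fs} Hz by more than 0.1%")
    return Recording(samples=x, fs=fs, adc_range=tuple(cm["adc_range"]),
                     label=cm["label"], units=cm["units"])


def read_session(path: str | os.PathLike) -> PairedSession:
    """Read a session written by :func:`write_session`.

    Metadata is validated strictly: a missing or malformed sidecar,
    NaN rows, a non-monotonic time column, or a time step inconsistent
    with the declared sampling rate all raise :class:`SessionFormatError`.
    """
    path = Path(path)
    mpath = path / METADATA_FILE
    if not mpath.exists():
        raise SessionFormatError(f"missing {METADATA_FILE} in {path}")
    with open(mpath) as fh:
        meta = yaml.safe_load(fh)
    for key in ("format", "fs", "channels"):
        if key not in meta:
            raise SessionFormatError(f"{METADATA_FILE}: missing required key '{key}'")
    fs = float(meta["fs"])
    chans = meta["channels"]
    for slot in ("ref", "exp", "sync_trigger", "sync_response"):
        if slot not in chans:
            raise SessionFormatError(f"{METADATA_FILE}: missing channel entry '{slot}'")

    loaded: dict[str, Optional[Recording]] = {}
    for slot, cm in chans.items():
        if cm is None:
            loaded[slot] = None
            continue
        for key in ("file", "label", "units", "adc_range"):
            if key not in cm:
                raise SessionFormatError(
                    f"{METADATA_FILE}: channel '{slot}' missing key '{key}'")
        loaded[slot] = _read_channel(path, cm["file"], fs, cm)

    if loaded.get("ref") is None or loaded.get("exp") is None:
        raise SessionFormatError("session must contain both 'ref' and 'exp' channels")

    gt = None
    gpath = path / GROUND_TRUTH_FILE
    if gpath.exists():
        with open(gpath) as fh:
            gt = GroundTruth.from_dict(json.load(fh))

    return PairedSession(
        ref=loaded["ref"],
        exp=loaded["exp"],
        sync_trigger=loaded["sync_trigger"],
        sync_response=loaded["sync_response"],
        ground_truth=gt,
        meta=meta.get("meta", {}) or {},
    )
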