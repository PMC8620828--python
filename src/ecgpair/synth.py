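"""Synthetic paired-session generator with known ground truth.

Emulates the statistical structure the validation pipeline assumes: a
clean Lead-I-like reference ECG, a degraded experimental channel sharing
the same underlying heartbeat sequence, a constant clock lag (with
optional linear drift) between the two devices, and acoustic sync pulses
present on both sync channels.

The beat waveform is a sum of five Gaussians (P, Q, R, S, T), and the
inter-beat (RR) process is an AR(1) deviation around the mean interval
whose variance and lag-1 correlation are tuned to hit target SDNN and
SDSD values — the two time-domain statistics the downstream HRV analysis
consumes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .sigio import GroundTruth, PairedSession, Recording

__all__ = [
    "RRSeries",
    "BeatTemplateParams",
    "DegradationSpec",
    "SessionConfig",
    "generate_rr_series",
    "synthesize_ecg",
    "apply_degradation",
    "generate_paired_session",
    "colored_noise",
    "generate_fractal_rr",
    "load_config",
]


@dataclass
class RRSeries:
    """A sequence of inter-beat intervals in milliseconds."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if self.intervals.size and np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def mean_hr(self) -> float:
        """Mean heart rate in BPM implied by the mean interval."""
        return 60000.0 / float(np.mean(self.intervals))


# (amplitude mV, center offset from R in ms, Gaussian width in ms)
_DEFAULT_WAVES = {
    "P": (0.15, -170.0, 22.0),
    "Q": (-0.10, -28.0, 9.0),
    "R": (1.00, 0.0, 11.0),
    "S": (-0.18, 28.0, 9.0),
    "T": (0.35, 230.0, 55.0),
}


@dataclass
class BeatTemplateParams:
    """Gaussian-sum P-QRS-T beat template.

    ``waves`` maps wave name to (amplitude mV, center offset from the
    R peak in ms, Gaussian width in ms).
    """

    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_WAVES))

    def __post_init__(self) -> None:
        if "R" not in self.waves:
            raise ValueError("template must contain an R wave")
        if self.waves["R"][0] <= 0:
            raise ValueError("R amplitude must be positive")
        for name, (_, _, width) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name}: width must be positive")

    @property
    def r_amplitude(self) -> float:
        return self.waves["R"][0]

    @property
    def span_ms(self) -> tuple[float, float]:
        """(earliest, latest) extent of the template relative to R, ms."""
        lo = min(c - 4 * w for _, c, w in self.waves.values())
        hi = max(c + 4 * w for _, c, w in self.waves.values())
        return lo, hi


@dataclass
class DegradationSpec:
    """Channel degradation description.

    Fields mirror the failure modes a dry-electrode acquisition shows:
    broadband noise, baseline wander, saturation/dropout episodes,
    amplitude scaling, low-pass morphology smearing (emulating the
    barrier layer a high-density skin moisturizer forms), and a clock
    lag/drift relative to the reference device.
    """

    snr_db: Optional[float] = None
    wander_amplitude_mv: float = 0.0
    wander_freq_hz: float = 0.25
    saturation_episodes: Sequence[tuple[float, float]] = ()  # (start s, duration s)
    gain: float = 1.0
    smear_cutoff_hz: Optional[float] = None
    lag_samples: float = 0.0
    drift_samples_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        eps = sorted((float(a), float(b)) for a, b in self.saturation_episodes)
        for (a, d) in eps:
            if d <= 0:
                raise ValueError("saturation episode duration must be positive")
        for (a1, d1), (a2, _) in zip(eps, eps[1:]):
            if a1 + d1 > a2:
                raise ValueError("saturation episodes must not overlap")
        self.saturation_episodes = tuple(eps)

    def validate_for(self, duration_s: float) -> None:
        for (a, d) in self.saturation_episodes:
            if a < 0 or a + d > duration_s:
                raise ValueError(
                    f"saturation episode ({a}, {d}) outside recording of {duration_s}s")

    @property
    def is_identity(self) -> bool:
        return (self.snr_db is None and self.wander_amplitude_mv == 0.0
                and not self.saturation_episodes and self.gain == 1.0
                and self.smear_cutoff_hz is None)


def generate_rr_series(mean_hr: float, sdnn_target: float, sdsd_target: float,
                       n_beats: int, seed: int) -> RRSeries:
    """Generate an RR series with target SDNN/SDSD via an AR(1) process.

    Deviations around the mean interval follow ``x_t = phi*x_{t-1} + e_t``
    with the innovation variance set so the stationary standard
    deviation equals ``sdnn_target`` and ``phi = 1 - SDSD^2/(2*SDNN^2)``
    so the successive-difference standard deviation equals
    ``sdsd_target``.  Deterministic for a given seed.

    Parameters are in BPM (``mean_hr``) and milliseconds (targets).
    """
    if n_beats < 2:
        raise ValueError("n_beats must be at least 2")
    if not (30.0 <= mean_hr <= 220.0):
        raise ValueError(f"mean_hr {mean_hr} outside plausible range [30, 220] BPM")
    if sdnn_target < 0 or sdsd_target < 0:
        raise ValueError("variability targets must be non-negative")

    mean_ms = 60000.0 / mean_hr
    if sdnn_target == 0.0:
        if sdsd_target > 0:
            raise ValueError("sdsd_target > 0 requires sdnn_target > 0")
        return RRSeries(np.full(n_beats, mean_ms))
    if sdsd_target >= 2.0 * sdnn_target:
        raise ValueError(
            "unattainable combination: an AR(1) RR process requires "
            f"SDSD < 2*SDNN (got SDSD={sdsd_target}, SDNN={sdnn_target})")
    if sdsd_target == 0.0:
        raise ValueError("sdsd_target must be positive when sdnn_target > 0")

    phi = 1.0 - sdsd_target**2 / (2.0 * sdnn_target**2)
    sigma_e = sdnn_target * np.sqrt(1.0 - phi**2)
    rng = np.random.default_rng(seed)
    x = np.empty(n_beats)
    x[0] = rng.normal(0.0, sdnn_target)  # stationary start
    e = rng.normal(0.0, sigma_e, size=n_beats - 1)
    for i in range(1, n_beats):
        x[i] = phi * x[i - 1] + e[i - 1]
    intervals = mean_ms + x
    # physiologically impossible non-positive intervals are floored; with
    # realistic targets this never triggers
    np.clip(intervals, 0.05 * mean_ms, None, out=intervals)
    return RRSeries(intervals)


def synthesize_ecg(rr: RRSeries, fs: float,
                   template: Optional[BeatTemplateParams] = None,
                   duration_s: Optional[float] = None,
                   adc_range: tuple[float, float] = (-5.0, 5.0),
                   ) -> tuple[Recording, np.ndarray]:
    """Render an ECG from an RR series as a train of Gaussian-sum beats.

    The i-th R peak sits at the cumulative sum of the first i intervals,
    so ``len(rr)`` beats produce exactly ``len(rr)`` R peaks and the
    first beat is preceded by one interval of lead-in.  Returns the
    recording and the true R-peak sample indices.
    """
    if len(rr) == 0:
        raise ValueError("empty RR series")
    template = template or BeatTemplateParams()
    if fs < 100.0:
        raise ValueError(f"fs={fs} Hz too low to resolve QRS morphology")
    min_width_ms = min(w for _, _, w in template.waves.values())
    if fs < 2000.0 / min_width_ms:
        raise ValueError(
            f"fs={fs} Hz cannot resolve the narrowest wave ({min_width_ms} ms)")

    r_times_s = np.cumsum(rr.intervals) / 1000.0
    _, tail_ms = template.span_ms
    if duration_s is None:
        duration_s = r_times_s[-1] + tail_ms / 1000.0
    n = int(round(duration_s * fs))
    x = np.zeros(n)
    keep = r_times_s * fs <= n - 1
    r_times_s = r_times_s[keep]

    lo_ms, hi_ms = template.span_ms
    for t_r in r_times_s:
        a = max(0, int(np.floor((t_r + lo_ms / 1000.0) * fs)))
        b = min(n, int(np.ceil((t_r + hi_ms / 1000.0) * fs)) + 1)
        tt = (np.arange(a, b) / fs - t_r) * 1000.0  # ms relative to R
        for amp, center, width in template.waves.values():
            x[a:b] += amp * np.exp(-0.5 * ((tt - center) / width) ** 2)

    r_idx = np.round(r_times_s * fs).astype(int)
    rec = Recording(samples=x, fs=fs, adc_range=adc_range, label="ecg")
    return rec, r_idx


def _episode_slices(episodes, fs: float) -> list[slice]:
    out = []
    for start, dur in episodes:
        a = int(round(start * fs))
        b = a + int(round(dur * fs))
        out.append(slice(a, b))
    return out


def apply_degradation(rec: Recording, spec: DegradationSpec, seed: int,
                      ) -> tuple[Recording, np.ndarray]:
    """Apply a degradation spec to a recording.

    Stage order: morphology smear (zero-phase low-pass), gain, baseline
    wander, additive white noise at the requested SNR (relative to the
    in-band signal power at that stage), then saturation — episode
    samples are railed to the upper ADC bound and flagged invalid in the
    returned mask; finally the whole signal is clipped to the ADC range.
    Deterministic given the seed.
    """
    spec.validate_for(rec.duration)
    rng = np.random.default_rng(seed)
    x = rec.samples.copy()

    if spec.smear_cutoff_hz is not None:
        b, a = sps.butter(4, spec.smear_cutoff_hz, btype="low", fs=rec.fs)
        x = sps.filtfilt(b, a, x)
    if spec.gain != 1.0:
        x = x * spec.gain
    signal_power = float(np.mean(x**2))
    if spec.wander_amplitude_mv:
        t = rec.times()
        phase = rng.uniform(0.0, 2.0 * np.pi)
        x = x + spec.wander_amplitude_mv * np.sin(
            2.0 * np.pi * spec.wander_freq_hz * t + phase)
    if spec.snr_db is not None:
        sigma = np.sqrt(signal_power / 10.0 ** (spec.snr_db / 10.0))
        x = x + rng.normal(0.0, sigma, size=x.size)

    mask = np.zeros(x.size, dtype=bool)
    lo, hi = rec.adc_range
    for sl in _episode_slices(spec.saturation_episodes, rec.fs):
        x[sl] = hi
        mask[sl] = True
    np.clip(x, lo, hi, out=x)
    return rec.copy_with(samples=x), mask


@dataclass
class SessionConfig:
    """Everything needed to generate one synthetic paired session."""

    duration_s: float = 900.0
    fs: float = 1000.0
    adc_range: tuple[float, float] = (-5.0, 5.0)
    mean_hr: float = 75.0
    sdnn_ms: float = 50.0
    sdsd_ms: float = 30.0
    template: BeatTemplateParams = field(default_factory=BeatTemplateParams)
    ref_degradation: DegradationSpec = field(default_factory=DegradationSpec)
    exp_degradation: DegradationSpec = field(default_factory=DegradationSpec)
    sync_times_s: Sequence[float] = (10.0, 450.0, 890.0)
    sync_pulse_width_s: float = 0.05
    sync_pulse_amplitude: float = 1.0
    sync_noise_floor: float = 0.005
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "template" in d and not isinstance(d["template"], BeatTemplateParams):
            d["template"] = BeatTemplateParams(
                waves={k: tuple(v) for k, v in d["template"].items()})
        for key in ("ref_degradation", "exp_degradation"):
            if key in d and not isinstance(d[key], DegradationSpec):
                dd = dict(d[key])
                if "saturation_episodes" in dd:
                    dd["saturation_episodes"] = [tuple(e) for e in dd["saturation_episodes"]]
                d[key] = DegradationSpec(**dd)
        if "adc_range" in d:
            d["adc_range"] = tuple(d["adc_range"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> SessionConfig:
    """Load a :class:`SessionConfig` from a YAML file."""
    import yaml
    with open(path) as fh:
        return SessionConfig.from_dict(yaml.safe_load(fh) or {})


def _pulse_train(n: int, fs: float, starts_samples: np.ndarray, width_s: float,
                 amplitude: float, noise_floor: float,
                 rng: np.random.Generator) -> np.ndarray:
    x = rng.normal(0.0, noise_floor, size=n) if noise_floor > 0 else np.zeros(n)
    w = max(1, int(round(width_s * fs)))
    for s in starts_samples:
        # nearest sample: keeps onset quantization centered so the
        # event-regression intercept stays within one sample of truth
        a = int(np.round(s))
        if a >= n:
            continue
        x[a:min(n, a + w)] += amplitude
    return x


def generate_paired_session(config: SessionConfig,
                            seed: Optional[int] = None) -> PairedSession:
    """Generate the four-channel layout: trigger (O1), reference ECG,
    microphone response (MIC), and experimental ECG.

    The experimental device's clock is offset from the reference clock
    by ``lag + drift*t`` samples (taken from the experimental channel's
    :class:`DegradationSpec`), and both sync channels carry pulse trains
    whose per-event offset equals that clock offset.  The returned
    session carries full :class:`~ecgpair.sigio.GroundTruth`.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=4)
    fs = config.fs
    n = int(round(config.duration_s * fs))

    lag = config.exp_degradation.lag_samples
    drift = config.exp_degradation.drift_samples_per_s
    if abs(lag) >= n:
        raise ValueError(f"lag of {lag} samples exceeds recording length {n}")

    n_beats = int(np.ceil(config.duration_s * config.mean_hr / 60.0 * 1.3)) + 10
    rr = generate_rr_series(config.mean_hr, config.sdnn_ms, config.sdsd_ms,
                            n_beats, seed=int(sub[0]))
    clean, r_idx_ref = synthesize_ecg(rr, fs, config.template,
                                      duration_s=config.duration_s,
                                      adc_range=config.adc_range)

    # reference channel
    config.ref_degradation.validate_for(config.duration_s)
    ref, mask_ref = apply_degradation(clean, config.ref_degradation, seed=int(sub[1]))
    ref = ref.copy_with(label="ecg_ref")

    # experimental channel: resample the physical waveform onto the
    # experimental clock (sample m records reference time t solving
    # m = t*fs + lag + drift*t), then degrade sensor-side
    m = np.arange(n)
    t_phys = (m - lag) / (fs + drift)
    exp_clean_samples = np.interp(t_phys, clean.times(), clean.samples,
                                  left=0.0, right=0.0)
    exp_clean = clean.copy_with(samples=exp_clean_samples, label="ecg_exp")
    exp_spec = copy.deepcopy(config.exp_degradation)
    exp, mask_exp = apply_degradation(exp_clean, exp_spec, seed=int(sub[2]))

    # sync channels: trigger on the reference clock, response on the
    # experimental clock, offset by lag + drift*t
    sync_times = np.asarray(config.sync_times_s, dtype=float)
    if np.any((sync_times < 0) | (sync_times > config.duration_s)):
        raise ValueError("sync pulse times must lie within the session duration")
    rng_sync = np.random.default_rng(int(sub[3]))
    trig_starts = sync_times * fs
    resp_starts = sync_times * fs + lag + drift * sync_times
    au_range = (-2.0 * config.sync_pulse_amplitude, 2.0 * config.sync_pulse_amplitude)
    trig = Recording(
        _pulse_train(n, fs, trig_starts, config.sync_pulse_width_s,
                     config.sync_pulse_amplitude, config.sync_noise_floor, rng_sync),
        fs=fs, adc_range=au_range, label="o1", units="au")
    resp = Recording(
        _pulse_train(n, fs, resp_starts, config.sync_pulse_width_s,
                     config.sync_pulse_amplitude, config.sync_noise_floor, rng_sync),
        fs=fs, adc_range=au_range, label="mic", units="au")

    tau = r_idx_ref / fs  # true beat times on the reference clock
    r_exp = np.round(tau * fs + lag + drift * tau).astype(int)
    inside = (r_exp >= 0) & (r_exp < n)
    gt = GroundTruth(
        r_peaks_ref=r_idx_ref,
        r_peaks_exp=r_exp[inside],
        invalid_mask_ref=mask_ref,
        invalid_mask_exp=mask_exp,
        lag=float(lag),
        drift=float(drift),
        sync_times=sync_times,
    )
    return PairedSession(ref=ref, exp=exp, sync_trigger=trig, sync_response=resp,
                         ground_truth=gt, meta={"seed": int(seed)})


def colored_noise(beta: float, n: int, seed: int | np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectrum ~ 1/f^beta.

    beta=0 is white noise, beta=1 is 1/f (pink) noise, beta=2 has
    random-walk-like scaling.  Spectral synthesis with Gaussian random
    phases; deterministic given the seed.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-beta / 2.0)
    phases = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    x = np.fft.irfft(amp * phases, n)
    return (x - x.mean()) / x.std()


def generate_fractal_rr(alpha: float, n_beats: int, mean_ms: float = 1000.0,
                        sd_ms: float = 50.0, seed: int = 0) -> RRSeries:
    """RR series whose detrended-fluctuation exponent is ``alpha``.

    Uses 1/f^beta noise with beta = 2*alpha - 1 (alpha 0.5 -> white,
    1.0 -> pink, 1.5 -> random-walk scaling).
    """
    x = colored_noise(2.0 * alpha - 1.0, n_beats, seed)
    intervals = mean_ms + sd_ms * x
    np.clip(intervals, 0.05 * mean_ms, None, out=intervals)
    return RRSeries(intervals)
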