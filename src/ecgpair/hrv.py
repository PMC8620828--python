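"""Heart-rate-variability analysis: time domain, Poincaré geometry, and DFA.

The Poincaré plot scatters each NN interval against the next; SD1 and
SD2 are the scatter's dispersions along the -45 and +45 degree axes,

    SD1 = sqrt(SDSD^2 / 2)
    SD2 = sqrt(2*SDNN^2 - SDSD^2 / 2)
    SD_ratio = SD1/SD2,   S = pi * SD1 * SD2  (ellipse area)

with SDSD the standard deviation of successive NN differences and SDNN
the standard deviation of the intervals.  For SD2 the SDNN term is
taken over the lag-1 scatter's two marginals, which makes the formula
*exactly* the +45-degree projection of the scatter (the full-series
SDNN differs by O(1/n) and is reported separately).

DFA integrates the mean-centered series, splits it into non-overlapping
windows of size n, removes a linear trend per window, and reads the
Hurst-type exponent alpha as the slope of log F(n) versus log n, with
the conventional short (4-16 beats, alpha1) and long (16-64, alpha2)
ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .qrs import BeatAnnotation
from .synth import RRSeries

__all__ = ["PoincareSummary", "DFAResult", "nn_intervals", "poincare",
           "ellipse_area", "dfa", "hrv_record"]


@dataclass
class PoincareSummary:
    SDNN: float      # ms, full-series standard deviation of NN
    SDSD: float      # ms, standard deviation of successive differences
    SD1: float       # ms, minor (short-term) axis
    SD2: float       # ms, major (long-term) axis
    SD_ratio: float  # SD1/SD2, dimensionless
    S_area: float    # ms^2, pi*SD1*SD2


@dataclass
class DFAResult:
    window_sizes: np.ndarray   # beats
    fluctuations: np.ndarray   # ms
    alpha1: float              # slope over the short range
    alpha2: float              # slope over the long range
    short_range: tuple[int, int]
    long_range: tuple[int, int]


def nn_intervals(ann: BeatAnnotation, ectopy_filter_pct: float | None = None,
                 ) -> RRSeries:
    """NN intervals (ms) from an R-peak annotation.

    No ectopy filtering by default; with ``ectopy_filter_pct`` set,
    intervals differing from the previous kept interval by more than
    that percentage are dropped.
    """
    if len(ann) < 2:
        raise ValueError("need at least 2 peaks to form an interval")
    nn = np.diff(ann.times_ms())
    if ectopy_filter_pct is not None:
        kept = [nn[0]]
        for v in nn[1:]:
            if abs(v - kept[-1]) <= ectopy_filter_pct / 100.0 * kept[-1]:
                kept.append(v)
        nn = np.asarray(kept)
    return RRSeries(nn)


def ellipse_area(sd1: float, sd2: float) -> float:
    """Poincaré ellipse area S = pi * SD1 * SD2 (ms^2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SD1 and SD2 must be non-negative")
    return float(np.pi * sd1 * sd2)


def poincare(nn: RRSeries) -> PoincareSummary:
    """Poincaré descriptors of an NN series (sample, n-1, denominators)."""
    x = nn.intervals
    if x.size < 3:
        raise ValueError("need at least 3 intervals for Poincaré analysis")
    sdnn = float(np.std(x, ddof=1))
    diffs = np.diff(x)
    sdsd = float(np.std(diffs, ddof=1))
    # SDNN over the lag-1 scatter's marginals makes SD2 the exact
    # +45-degree projection (rotation preserves total scatter variance)
    sdnn_pair_sq = 0.5 * (np.var(x[:-1], ddof=1) + np.var(x[1:], ddof=1))
    sd1 = float(np.sqrt(0.5 * sdsd**2))
    sd2_sq = 2.0 * sdnn_pair_sq - 0.5 * sdsd**2
    # rounding can leave a tiny negative residue when SD2 is exactly 0
    if sd2_sq < -1e-9 * max(2.0 * sdnn_pair_sq, 1.0):
        raise ValueError("degenerate NN series: SD2^2 negative "
                         "(short-term variability exceeds total scatter)")
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    ratio = sd1 / sd2 if sd2 > 0 else (0.0 if sd1 == 0 else float("inf"))
    return PoincareSummary(SDNN=sdnn, SDSD=sdsd, SD1=sd1, SD2=sd2,
                           SD_ratio=ratio, S_area=ellipse_area(sd1, sd2))


def _window_sizes(lo: int, hi: int, per_decade: int = 16) -> np.ndarray:
    n_pts = max(3, int(np.ceil(np.log10(hi / lo) * per_decade)))
    return np.unique(np.round(np.geomspace(lo, hi, n_pts)).astype(int))


def dfa(nn: RRSeries, short_range: tuple[int, int] = (4, 16),
        long_range: tuple[int, int] = (16, 64)) -> DFAResult:
    """First-order detrended fluctuation analysis of an NN series.

    Windows are log-spaced integers covering both ranges; each window
    size partitions the integrated series into non-overlapping windows
    (trailing remainder discarded) that are linearly detrended, and
    F(n) is the RMS residual over all retained points.  alpha1/alpha2
    are least-squares slopes of log F versus log n over the short and
    long range; each range must contain at least 3 window sizes.
    """
    x = nn.intervals
    lo = min(short_range[0], long_range[0])
    hi = max(short_range[1], long_range[1])
    if x.size < 2 * hi:
        raise ValueError(
            f"series of {x.size} intervals too short for windows up to {hi}")
    if np.ptp(x) == 0:
        raise ValueError("constant series: fluctuation is zero, log undefined")

    sizes = _window_sizes(lo, hi)
    y = np.cumsum(x - np.mean(x))
    F = np.empty(sizes.size)
    for idx, n in enumerate(sizes):
        k = y.size // n
        seg = y[: k * n].reshape(k, n)
        t = np.arange(n, dtype=float)
        tc = t - t.mean()
        denom = float(np.sum(tc**2))
        slope = seg @ tc / denom
        mean = seg.mean(axis=1)
        resid = seg - (mean[:, None] + slope[:, None] * tc)
        F[idx] = np.sqrt(np.mean(resid**2))

    def fit(rng: tuple[int, int]) -> float:
        sel = (sizes >= rng[0]) & (sizes <= rng[1])
        if np.count_nonzero(sel) < 3:
            raise ValueError(f"fewer than 3 window sizes in range {rng}")
        return float(np.polyfit(np.log(sizes[sel]), np.log(F[sel]), 1)[0])

    return DFAResult(window_sizes=sizes, fluctuations=F,
                     alpha1=fit(short_range), alpha2=fit(long_range),
                     short_range=tuple(short_range), long_range=tuple(long_range))


def hrv_record(pc: PoincareSummary, df: DFAResult | None = None) -> dict:
    """Flat JSON-ready record keyed by the conventional column names."""
    rec = {
        "SD1": pc.SD1,
        "SD2": pc.SD2,
        "S": pc.S_area,
        "SD1/SD2": pc.SD_ratio,
    }
    if df is not None:
        rec["α1"] = df.alpha1
        rec["α2"] = df.alpha2
    return rec
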