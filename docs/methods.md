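# Methods

This note records the models, conventions and numerical choices behind
`ecgpair`, and what the synthetic-data results do and do not show about
real recordings.

## Synthetic paired sessions

**Beat model.** Each heartbeat is a sum of five Gaussians (P, Q, R, S,
T), parameterized per wave by amplitude (mV), center offset from the R
peak (ms) and width (ms). Defaults produce a Lead-I-like beat with a
1 mV R wave; the i-th R peak sits at the cumulative sum of the first i
RR intervals, so the true peak index is known exactly. This is adequate
for everything the pipeline measures (peak timing, window-level beat
shape); it contains no respiratory modulation of amplitude, no ectopy,
and no inter-beat morphology variation, so morphology scores on clean
synthetic data are optimistic relative to real skin-contact recordings.

**RR process.** Deviations around the mean interval follow an AR(1)
process `x_t = φ·x_{t−1} + ε_t`. Two targets pin its two parameters:
the stationary SD equals the SDNN target, and
`φ = 1 − SDSD²/(2·SDNN²)` makes the successive-difference SD equal the
SDSD target. An AR(1) process can only realize `SDSD < 2·SDNN`;
combinations outside that region are rejected. Defaults (75 BPM,
SDNN 50 ms, SDSD 30 ms) are typical resting adult values. Realized
statistics converge to the targets as 1/√n; the suite checks 5% at
n = 2000. Intervals are floored at 5% of the mean as a guard; with
realistic targets the floor is never reached.

**Clock model.** The experimental device's sample m records reference
time t solving `m = t·fs + lag + drift·t`, i.e. the offset in samples
grows linearly: `offset(t) = lag + drift·t`. Both sync channels carry
rectangular 50 ms pulses (amplitude 1, small Gaussian noise floor)
placed at the nearest sample to their true start; nearest-sample
placement keeps onset quantization centered so event-pairing recovers
the lag to within one sample. Linear drift only: over 15-minute
sessions higher-order clock error is not identifiable from a handful of
events.

**Degradations.** Applied sensor-side (after clock resampling), in
order: low-pass morphology smear (4th-order zero-phase Butterworth,
default cutoff 8 Hz — an emulation of the barrier layer a high-density
skin moisturizer forms, chosen to reproduce the qualitative blurring of
the P-QRS-T complex, not its physics), gain, baseline wander (single
sinusoid, random phase), white noise at a target SNR relative to the
signal power at that stage, then saturation: episode samples are railed
to the upper ADC bound and define the ground-truth invalid mask, and
the whole signal is clipped to the ADC range. Every stochastic step is
driven by a seeded generator; identical seeds give bit-identical
sessions.

**Defaults the source material leaves open.** The acquisition sampling
rate and ADC resolution of the device class are not published; we
default to fs = 1000 Hz and a ±5 mV range (ADC emulation is a clip to
that range; a 10-bit quantizer would add ~10 µV steps, irrelevant to
every statistic computed here, so samples stay continuous). The number
and schedule of sync pulses per session is a config choice (default
three: near the start, middle and end, which identifies both lag and
drift with maximal leverage).

## Synchronization

Event onsets: first sample where the rectified channel exceeds
`median + k·1.4826·MAD` (k = 8; the 1.4826 factor makes the MAD a
consistent σ estimate so k is in σ units), with a floor of 0.2× the
channel's rectified maximum so a noise floor cannot fire events when
real pulses are present; onsets within 1 s merge. Events are paired in
order; a count mismatch of one is resolved by dropping whichever end of
the longer list leaves the most consistent offsets. With ≥3 events the
offsets are regressed on trigger time — the intercept is the lag at
t = 0 (consistent with the generator's definition), the slope the
drift; with fewer events the lag is the median offset and drift 0.
Alignment linearly interpolates the experimental channels at positions
`k + lag + drift·k/fs` and keeps only the overlap region.

## Filtering and signal loss

The band-pass (3, 45) Hz choice (rather than a 45 Hz low-pass alone)
removes baseline wander before template comparison; both edges are
configurable. The default order scales with the sampling rate
(`~fs/2` taps): a fixed 30-tap window-design FIR has essentially no
stopband at a 3 Hz edge except near fs ≈ 100 Hz, where 30 taps matches
the common 0.3·fs convention. The filter is applied forward with the
group delay (order/2) compensated and reflection-padded edges, so
output length equals input length and R-peak latency is preserved.

Invalid-sample flagging: samples within a guard band (0.5% of range)
of either ADC bound, runs merged across <100 ms gaps, runs <50 ms
discarded. The signal detection error is reported in both orientations
— `valid = 100·(S−N)/S` and `loss = 100·N/S` — because both appear in
practice; the loss orientation is the headline "3–15%" style number.
They sum to 100 exactly by construction.

## QRS detection

Hamilton-style: detection function = 80 ms moving average of the
rectified first difference; candidate peaks ≥200 ms apart; threshold
`noise_avg + 0.3125·(qrs_avg − noise_avg)` over 8-deep running buffers
(initialized from the first 2 s: max → QRS seed, median → noise seed);
searchback accepts the best rejected candidate above half threshold
when the elapsed interval exceeds 1.5× the running RR mean. Detections
are refined to the local ECG maximum within ±100 ms. When an invalid
mask is supplied, the detection function is zeroed over the mask
dilated by the integration window and refinement cannot land on masked
samples — clip-edge filter transients otherwise masquerade as beats.
The parameters are the published open-source ones for this detector
family; all are exposed in `HamiltonParams`.

Matching is greedy nearest-neighbour within 100 ms, smallest time
difference first (ties: earlier peak), each peak used once — this makes
the pair set symmetric under swapping the channels. Heart rate uses
only intervals between *consecutive* matched pairs on both channels,
enforcing the matched-segment rule; QRS% is pairs over reference beats,
and spurious experimental detections are reported separately rather
than folded into QRS%.

## HRV

SDNN/SDSD use the sample (n−1) standard deviation, matching the common
HRV-library convention. SD1 is exactly `√(SDSD²/2)`. For SD2 the
`2·SDNN² − SDSD²/2` formula uses the SDNN over the lag-1 scatter's two
marginals, which makes SD2 *exactly* the +45° projection of the
Poincaré scatter (rotation preserves total scatter variance); with the
full-series SDNN the identity only holds to O(1/n). The summary still
reports the full-series SDNN. A degenerate series (negative SD2
argument beyond rounding) raises rather than returning an imaginary
axis; an exact-zero SD2 (e.g. a strictly alternating series) is clamped
from the −1e−9 rounding residue.

DFA: integrate the mean-centered series, partition into non-overlapping
windows (trailing remainder discarded), remove a per-window linear
trend, `F(n)` = RMS residual over retained points, and fit log F vs
log n by least squares. Window sizes are log-spaced integers; the
conventional short (4–16) and long (16–64) beat ranges give α1 and α2.
None of these conventions are forced by the underlying definition of
self-affinity — they are the standard HRV choices and are configurable.
First-order DFA has a known small-window bias (white noise reads
α ≈ 0.6 over 4–16), so exponent-recovery checks use the full 4–64
range, where white/1f/random-walk inputs read ≈0.54/1.01/1.51 at
n = 10000.

## Morphology

Window (−200, +400) ms around R covers P-QRS-T at resting rates;
per-beat baseline = mean of the first 40 ms of the window. The outlier
screen is a reconstruction — the source material defers its criterion
to an unavailable reference — using two rules against a median
template: cosine similarity < 0.8, or peak-to-peak outside [0.5, 2]× the
median; the template is recomputed from survivors once (two passes).
NRMSE is normalized by the reference beat's peak-to-peak range and
reported in percent; the published magnitudes (~20–60) are consistent
with a percent-of-range scale, but the normalizer is not stated there —
treat cross-study NRMSE comparisons with care. PCC is invariant to
affine rescaling of either beat, so electrode gain differences do not
depress it; NRMSE is not, by design.

## Pipeline and reporting

Stages run sync → preprocess → detection/matching → (HRV, morphology);
each stage contributes either a result or an explicit skip record with
the reason, so a fully saturated channel still yields its quality row.
Reports serialize as sorted-key JSON with no timestamps: identical
session + config ⇒ byte-identical reports. Provenance carries the
config hash (sha256 of the canonical config JSON), generator seed, and
package version. Impedance is a standalone calculator because the
bench measurement (oscilloscope amplitudes across a 1 kΩ divider) never
touches the ECG path.

## Problem sizes in the test suite

The suite exercises the pipeline at desk scale: 60–120 s sessions for
detector and rhythm checks (20 seeded sessions for the Se/PPV gate; at
75 BPM a 60 s session carries ~75 beats), one 900 s session for the
signal-loss construction, n = 10000-interval series for DFA recovery,
and 100 random series for the Poincaré oracle equivalence. These sizes
give the recovery statistics comfortable margins over their tolerances
while the whole suite runs in seconds.

## Known limitations

- The generator's beats are identical within a session up to channel
  degradation; real beat-to-beat morphology variation (respiration,
  posture, electrode micro-motion) is absent, so passing morphology
  tests show correctness of the *scoring*, not achievable field PCC.
- No arrhythmia or ectopy model; the matched-segment rule is exercised
  by dropouts, not ectopic displacement.
- Baseline wander is a single sinusoid; real wander is broadband.
- The sync scheme assumes the pulse is sharp relative to min_separation
  and that both transducers capture the same acoustic onset; transducer
  group delay differences fold directly into the estimated lag.
- Frequency-domain HRV (LF/HF) is out of scope.
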