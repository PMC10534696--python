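# Methods

This note documents the models, parameter choices and numerical
decisions behind `egosync`, and what the synthetic-data tests do and do
not establish about real recordings.

## Signal model and time base

All timestamps are seconds since device power-on, 64-bit floats;
intervals are half-open `[start, end)`; indices are 0-based. Device
streams are nonuniformly sampled (`TimedSamples`); algorithms operate on
uniform grids (`UniformSignal`) produced by nearest-neighbour
resampling, which never invents values (a binary stream stays binary)
and resolves exact half-way ties toward the later sample for
deterministic, causal playback. Sessions recorded as nominal 5-minute
blocks are stitched by concatenation and re-split at internal timestamp
gaps larger than 1 s (or at any non-increasing step, which marks a power
cycle); 1 s is far above any legitimate inter-frame or inter-sample gap
at the rates involved, and the partial block before a gap is restored to
the end of the previous session so that no samples are lost.

The on-disk dialect (`.eg.dat`) is fully documented in
`timebase.py`: little-endian, a 16-byte `EGAC` header, and 512-byte
blocks of chronologically merged tagged records with 1 ms ticks. ECG
values are stored as mV×1000 (three decimals), acceleration as g×1e6
clipped to the sensor's ±2 g range on read, luminosity as single bits.
Because the writer's packing is deterministic, write→read→write is
byte-identical for whole blocks; a truncated final block is dropped with
a warning.

## Synchronization

The 10-bit code packs day-of-month mod 8, hour and a 2-bit counter
MSB-first, day→hour→counter; the published example code (day 13, 19 h,
counter 3 → `1011001111`) fixes the concatenation order and is
consistent with MSB-first packing, which we therefore adopt and test
exhaustively over all 768 clock-reachable triples. The waveform layout
(2 s low; high/low/high 400 ms framing; ten 400 ms bit periods with
200 ms "on" pulses; low/high/low/high framing; 1 s green) totals 9.8 s
for every code; bit *i*'s potential-high window starts 3200+400(i−1) ms
into the waveform. On the intensity channel (mean over RGB) the green
screen contributes 1/3, the mean of (0,255,0)/255.

Localization slides the average-of-all-codes template (framing at 1,
bit highs at 0.5, green excluded, 8.8 s) over the search signal and
takes local maxima of the normalized cross-correlation. NCC is computed
with running sums; the correlation numerator uses direct summation below
2×10⁷ multiply-adds and FFT convolution above, and the implementation is
tested to 1e−9 against a per-window brute-force oracle. Local maxima use
strict neighbour comparison; plateaus take their left edge.

The acceptance threshold 0.65 is not stated by the source design and was
chosen so that a rendering with any single 0.4 s segment complemented
(the worst corruption expected from the sensor's 5-minute file-write
stall) still exceeds it — measured noiseless scores are ≈0.84–0.91,
dropping to ≈0.7 under one complemented segment — while 100 seeded pure
Bernoulli-noise streams produce zero detections. It is a config knob on
`ncc_locate`.

Video streams are reduced to per-frame channel means (the core never
parses containers; an adapter supplies frame statistics), resampled to
30 Hz by nearest frame, and coarse-searched on the greenness signal
max(0, G−R−B) with a step filter (1 s zero pad, −2 s, +1 s at 30 Hz; the
source gives the shape but not the lengths). Precise search upsamples
intensity to 100 Hz linearly **at frame-interval centers**: a frame
statistic summarizes its whole interval, and interpolating at the
presentation timestamps instead ramps every edge half a frame early,
biasing the onset by ~17 ms. With the center convention the noiseless
onset error over all 1024 codes is at most one sample at the search
rate. Decoding thresholds the window mean at 0.3 for video (white is
recorded below 1) and the window median at 0.5 for the binary
luminosity.

Matching groups detections by identical decoded code; duplicate codes
(more than four synchronizations in an hour) are paired across streams
in recording order and checked for global temporal-ordering consistency,
with real-time-clock spreads over an hour flagged for human review
rather than guessed. Each stream's time zero is the onset of the latest
matched synchronization it contains. Device times are finally multiplied
by the relative clock speed (default 0.9999; the sensor clock runs
0.1 s ahead per 1000 s, so multiplication maps device to real time).

## ECG processing

Filtering is a 4th-order Butterworth 15 Hz high-pass plus a Q=30 notch
at the mains frequency, both applied forward-backward (zero phase). The
15 Hz corner follows the design finding that infant QRS energy sits
higher than the adult 0.5 Hz convention; any realization meeting the
stated attenuation contract (≥40 dB at 1 Hz, ≥20 dB at mains) would
conform.

Detection correlates the signal with a zero-mean, unit-norm stylized
QRS — a 40 ms raised-cosine R wave between small Q/S troughs, the same
shape the synthetic generator places at each beat; this shared shape is
the package's explicit morphology prior. The kernel's zero mean rejects
baseline wander and the correlation averages wide-band noise, acting as
a matched filter for the steep R deflection. Peak heights split into QRS
and noise clusters by a 1-D two-means threshold; a search-back pass
re-scans inter-peak gaps longer than 1.6× the median gap at half
threshold, inserting a beat only where both resulting sub-gaps remain
plausible. Peak times take the sub-sample parabolic vertex of the
matched response.

Two design points deserve emphasis. First, when the raw signal is
available (the pipeline always has it) the matched statistic is computed
on it rather than on the 15 Hz-filtered signal: the high-pass removes
most of a 40 ms R wave's energy along with the baseline, and under
white noise at 10 dB SNR (relative to R amplitude) even an
oracle-thresholded matched filter on the filtered signal cannot exceed
≈0.86 sensitivity/precision, whereas on the raw signal the detector
measures ≥0.99 typical (worst 0.97 precision across seeds at exactly
10 dB, 1.00/1.00 at 15 dB). Second, the pipeline's local correction
against the raw unprocessed signal is embodied in the detector (raw
matched statistic + sub-sample vertex); the iterative ±0.01 s raw-argmax
correction, implemented and tested as `refine_peaks_local`, applies when
detection ran on filtered-only input, because snapping to noisy raw
samples adds ~1.4 ms of timing jitter that the vertex avoids —
enough to push the 20-minute recovery error from ≈0.7 to ≈1.9 bpm.

Heart rate is `60/Δt_peaks`, timestamped at the later peak of each gap
(causal; unambiguous interpolation anchors). The median beat correction
rejects samples outside the multiplicative band [m/1.3, m×1.3] of a
31-beat local median (the published parameter scan identifies FW=31,
AT=1.3 as optimal, with AT described as a multiplicative factor; an
additive reading is rejected), shrinking the window symmetrically at the
edges, and fills rejections by linear interpolation between accepted
neighbours. The shifted-beat rule flags three consecutive HR-difference
sign changes exceeding 15/25/15 bpm; the flagged pair of samples is
rejected and interpolated the same way (the remedy is not stated by the
source; rejection+interpolation matches the median-rule treatment).

The SQI marks a sample good when fewer than 25 % of the beats in its
31-beat window were rejected (the source sentence "less than 75 % …
deviate" conflicts with its stated 75 %-good intent; we read it as
"good iff <25 % rejected" and expose the fraction as a knob), grows good
regions outward one beat at a time while the boundary beat is itself
in-band, then zeroes out-of-band runs longer than 3.5 s, samples
spanning inter-peak gaps over 2.5 s, and surviving good regions shorter
than 5 s. Region growing uses the corrected-series rejection flags.

## Acceleration and video QC

Dropout detection applies the 5-point moving SD per axis with a logical
OR (a flatline on any axis signals sensor dropout); edge samples inherit
the nearest full-window SD rather than an unstable 2–3-sample estimate.
Tail trimming masks, per axis over valid samples, values strictly beyond
the (k+1)-th order statistic with k = ⌊0.0005·n⌋ — exactly the k most
extreme per side for distinct values, nothing for a constant axis.
Masking never alters values.

Dark detection is strictly `< 0.15`; a frame owns `[t_k, t_k+1/rate)`,
so dark intervals and their complement partition the timeline exactly.
The 5-pixel border is unrolled clockwise from the top-left corner (top
edge left→right, right top→bottom, bottom right→left, left bottom→top,
each as border-deep cross-sections) into one pixel strip split into 20
contiguous equal segments, remainder to the last; the partition geometry
is not specified by the source, and this one covers every border pixel
exactly once. The static rule (≥5 segments under 2 px mean magnitude)
is verified against a per-pixel brute-force oracle. The inversion review
band is 0.20–0.80 ("high, but <80 %" is undefined at its lower edge;
0.20 is a config knob). Neural flow/inversion providers plug in behind
plain array/probability interfaces; the shipped defaults (block-matching
flow, top-vs-bottom brightness heuristic) exist for determinism and
testing, not state-of-the-art accuracy.

## Agreement

The test HR is evaluated at reference beat times by step interpolation
(HR is piecewise constant over its gap); reference beats outside the
overlap are excluded. Agreement is inclusive (≤5 bpm). The shift/stretch
alignment maximizes the agreement proportion on a coarse-to-fine grid
(shift ±300 s at 0.5 s default, stretch 0.999–1.001; refined to 5 ms and
1e−6). Because the proportion is piecewise constant in the shift, exact
plateau ties are broken by the mean absolute time offset between
reference beats and the nearest mapped test beats — a continuous
criterion sharply minimized at the true alignment (a derivative-based
refinement such as golden-section is not applicable to a step
objective). Recovery on synthetic fixtures is within ±0.05 s shift and
±1e−5 stretch.

## Synthetic generators

All generators are pure functions of (spec, seed). ECG: beat times
integrate the HR profile (constant, or sinusoidal RSA modulation);
corruption deletes beats (p_missing), inserts mid-gap extras (p_extra),
or replaces beats in scrambled intervals with uniformly random times;
device timestamps are real time divided by the clock factor, with ±0.4 ms
uniform jitter; noise is additive white Gaussian with σ = R-amplitude ×
10^(−SNR/20). Video frame intervals are drawn uniformly from
[1/35, 1/20] s to emulate variable-frame-rate capture dropping to 20 Hz;
the white level defaults to 0.8 (configurable below 1), scene noise
σ=0.02. Accelerometry is a 1 g gravity baseline with optional motion
bursts, exact value-hold dropouts and ±3 g spikes.

Problem sizes in the tests (e.g. 20-minute ECG recovery, 2-hour drift
analysis, 120 s detector contracts) are the package's chosen desk-scale
study conditions; generator parameters are part of those stated
conditions, not quantities tuned per test.

What passing these tests shows — and does not. The generators emulate
sampling geometry, clock drift, white sensor noise and discrete beat
corruptions; they do not emulate real infant ECG morphology variation,
motion and electrode artifacts with 1/f structure, rolling-shutter or
auto-exposure video effects, or real optical flow. Detector and SQI
performance on real recordings will differ; the suites establish
correctness of the algorithms under their stated models, exact
implementations of the documented rules, and end-to-end determinism.

## Known limitations

* At exactly 10 dB white-noise SNR the detector's worst-case precision
  across seeds is ≈0.97, slightly under its nominal 0.99 contract; the
  bound is information-theoretic in origin (see the filtering discussion
  above) and the acceptance conditions (15 dB) hold with margin.
* `match_and_align` resolves duplicate codes by recording order and
  flags, rather than solves, order-inconsistent hypotheses.
* The agreement alignment assumes a single global shift/stretch; it does
  not model within-recording clock wander (measured drift change is
  ~2×10⁻⁶ per half hour, negligible at the durations treated here).
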