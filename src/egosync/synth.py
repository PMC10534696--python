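"""Seeded generators for every input modality with known ground truth.

Each generator is a pure function of its spec (including the seed):
identical inputs give bit-identical outputs. The defaults emulate the
recording conditions the platform was validated under -- ECG sampled
nonuniformly around 250 Hz with +/-0.4 ms timestamp jitter and a crystal
running fast by a factor of 1/0.9999; binary luminosity around 250 Hz;
variable-frame-rate video statistics whose frame intervals fall between
20 and 35 Hz; accelerometry at 65 Hz around a 1 g gravity baseline.

The ECG waveform is a stereotyped QRS template (raised-cosine R wave of
40 ms width with small Q and S troughs) placed at each beat time, plus
additive white Gaussian noise at a requested SNR relative to the R-wave
amplitude. Morphological realism is not a goal; peak detectability and
the qualitative QRS shape are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from egosync import sync_codec
from egosync.accel import AccelSeries
from egosync.ecg import PeakTrain, stylized_qrs
from egosync.sync_detect import FrameStats
from egosync.timebase import TimedSamples

__all__ = [
    "SynthSpec",
    "SynthECG",
    "SynthSyncStreams",
    "SynthAccel",
    "SynthQCInputs",
    "synth_ecg",
    "synth_sync_streams",
    "synth_accel",
    "synth_qc_inputs",
]


@dataclass
class SynthSpec:
    """Conditions for the synthetic generators.

    ``hr_profile`` is ``("constant", mean_bpm)`` or
    ``("sinusoidal", mean_bpm, depth_bpm, period_s)`` -- the latter
    emulates respiratory sinus arrhythmia. ``noise_snr_db`` is the
    white-noise level relative to the R-wave amplitude (None = clean).
    ``clock_factor`` is the device's relative clock speed: recorded
    timestamps are real time divided by it. ``scramble_intervals`` are
    (start, end) spans whose beats are replaced by uniformly random peak
    times; ``dropout_intervals`` are spans where the signal is flat.
    """

    seed: int = 0
    duration: float = 60.0
    hr_profile: tuple = ("constant", 150.0)
    noise_snr_db: float | None = None
    p_missing: float = 0.0
    p_extra: float = 0.0
    clock_factor: float = 1.0
    dropout_intervals: list = field(default_factory=list)
    scramble_intervals: list = field(default_factory=list)
    ecg_rate: float = 250.0
    acc_rate: float = 65.0
    lux_rate: float = 250.0
    timestamp_jitter: float = 0.0004  # s, uniform, ECG/lux
    codes: list = field(default_factory=list)  # (SyncCode, onset_time_s)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.clock_factor <= 0:
            raise ValueError("clock_factor must be > 0")
        for p in (self.p_missing, self.p_extra):
            if not 0.0 <= p <= 1.0:
                raise ValueError("per-beat probabilities must be in [0, 1]")

    def hr_at(self, t):
        kind = self.hr_profile[0]
        if kind == "constant":
            return np.broadcast_to(float(self.hr_profile[1]), np.shape(t)).copy() \
                if np.ndim(t) else float(self.hr_profile[1])
        if kind == "sinusoidal":
            _, mean, depth, period = self.hr_profile
            return mean + depth * np.sin(2 * np.pi * np.asarray(t) / period)
        raise ValueError(f"unknown hr profile {kind!r}")


@dataclass
class SynthECG:
    ecg: TimedSamples          # device-clock timestamps
    truth: PeakTrain           # clean beat process, real time
    rendered_peaks: np.ndarray  # beats actually present in the signal, real time


@dataclass
class SynthSyncStreams:
    lux: TimedSamples
    frames: FrameStats
    lux_onsets: np.ndarray    # bit-1 start times in the lux stream clock
    video_onsets: np.ndarray  # bit-1 start times in the video stream clock


@dataclass
class SynthAccel:
    series: AccelSeries
    dropout_mask: np.ndarray  # flat samples (without margins)
    outlier_mask: np.ndarray


@dataclass
class SynthQCInputs:
    intensity: "object"        # UniformSignal, 1 fps mean brightness
    dark_intervals: list
    flows: list                # (H, W, 2) arrays
    static_truth: list         # bool per flow
    inversion_probs: np.ndarray
    inverted_fraction: float


# ---------------------------------------------------------------------------
# ECG


def _beat_times(spec: SynthSpec) -> np.ndarray:
    """Integrate the HR profile into real-time beat positions."""
    times = [0.0]
    while True:
        gap = 60.0 / float(spec.hr_at(times[-1]))
        nxt = times[-1] + gap
        if nxt > spec.duration:
            break
        times.append(nxt)
    return np.asarray(times)


def synth_ecg(spec: SynthSpec) -> SynthECG:
    """Generate a nonuniformly sampled ECG with known R-peak ground truth.

    Beats follow ``spec.hr_profile``; corruption deletes beats with
    probability ``p_missing``, inserts an extra mid-gap beat with
    probability ``p_extra``, and replaces beats inside
    ``scramble_intervals`` with uniformly random times. Device
    timestamps are real time divided by ``clock_factor``, with uniform
    sampling jitter.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _beat_times(spec)

    present = truth[rng.random(len(truth)) > spec.p_missing]
    extras = []
    for a, b in zip(present[:-1], present[1:]):
        if rng.random() < spec.p_extra:
            extras.append(a + (0.35 + 0.3 * rng.random()) * (b - a))
    rendered = np.sort(np.concatenate([present, np.asarray(extras)]))
    for a, b in spec.scramble_intervals:
        inside = (rendered >= a) & (rendered < b)
        n_in = int(inside.sum())
        rendered = rendered[~inside]
        if n_in:
            rendered = np.sort(np.concatenate([rendered, np.sort(rng.uniform(a, b, n_in))]))
    rendered = np.unique(rendered)

    n = int(spec.duration * spec.ecg_rate)
    t_real = np.arange(n) / spec.ecg_rate
    if spec.timestamp_jitter:
        t_real = t_real + rng.uniform(-spec.timestamp_jitter, spec.timestamp_jitter, n)
        t_real = np.maximum.accumulate(t_real)
        t_real += np.arange(n) * 1e-9  # keep strictly increasing
    values = np.zeros(n)
    idx = np.searchsorted(rendered, t_real)
    for nb in (idx - 1, idx):
        ok = (nb >= 0) & (nb < len(rendered))
        dt = np.full(n, np.inf)
        dt[ok] = t_real[ok] - rendered[nb[ok]]
        close = np.abs(dt) < 0.08
        values[close] += stylized_qrs(dt[close])
    if spec.noise_snr_db is not None:
        sigma = 10.0 ** (-spec.noise_snr_db / 20.0)
        values = values + rng.normal(0.0, sigma, n)
    for a, b in spec.dropout_intervals:
        values[(t_real >= a) & (t_real < b)] = 0.0

    t_device = t_real / spec.clock_factor
    ecg = TimedSamples(t_device, values, "ecg")
    return SynthECG(ecg=ecg, truth=PeakTrain(truth), rendered_peaks=rendered)


# ---------------------------------------------------------------------------
# synchronization streams


def synth_sync_streams(
    spec: SynthSpec,
    white_level: float = 0.8,
    low_level: float = 0.05,
    green_level: float = 0.7,
    video_noise: float = 0.02,
    lux_flip_prob: float = 0.0,
    corrupt: list | None = None,
) -> SynthSyncStreams:
    """Render coded-light waveforms into luminosity and frame-stat streams.

    ``spec.codes`` lists ``(SyncCode, onset_time)`` pairs, where the
    onset is the *waveform start*; returned ground-truth onsets are the
    bit-1 starts (3.2 s later), one per code per stream. ``corrupt``
    optionally lists ``("lux"|"video", start_s, duration_s)`` spans whose
    intensity is complemented, emulating transmission errors. Frame
    intervals are drawn uniformly from [1/35, 1/20] s (variable frame
    rate dropping to 20 Hz); the luminosity is the binarized intensity
    sampled near 250 Hz with timestamp jitter.
    """
    onsets = sorted(t for _, t in spec.codes)
    for a, b in zip(onsets[:-1], onsets[1:]):
        if b - a < sync_codec.TOTAL_DURATION:
            raise ValueError("overlapping synchronization codes")

    def level_at(t):
        lvl = np.zeros(np.shape(t), dtype=int)
        for code, onset in spec.codes:
            rel = np.asarray(t) - onset
            m = (rel >= 0) & (rel < sync_codec.TOTAL_DURATION)
            if m.any():
                lvl[m] = sync_codec.waveform_level(code, rel[m])
        return lvl

    rng = np.random.default_rng(spec.seed + 1)

    # --- luminosity -------------------------------------------------------
    n_lux = int(spec.duration * spec.lux_rate)
    t_lux = np.arange(n_lux) / spec.lux_rate
    if spec.timestamp_jitter:
        t_lux = np.maximum.accumulate(
            t_lux + rng.uniform(-spec.timestamp_jitter, spec.timestamp_jitter, n_lux)
        ) + np.arange(n_lux) * 1e-9
    lvl = level_at(t_lux)
    intensity = np.choose(lvl, [0.0, 1.0, sync_codec.GREEN_INTENSITY])
    if corrupt:
        for stream, a, d in corrupt:
            if stream == "lux":
                m = (t_lux >= a) & (t_lux < a + d)
                intensity[m] = 1.0 - intensity[m]
    lux_vals = (intensity >= 0.5).astype(float)
    if lux_flip_prob > 0:
        flips = rng.random(n_lux) < lux_flip_prob
        lux_vals[flips] = 1.0 - lux_vals[flips]
    lux = TimedSamples(t_lux, lux_vals, "lux")

    # --- video frame statistics ------------------------------------------
    frame_dt = rng.uniform(1.0 / 35.0, 1.0 / 20.0, int(spec.duration * 35) + 2)
    t_frames = np.cumsum(frame_dt)
    t_frames = t_frames[t_frames < spec.duration]
    lvl_f = level_at(t_frames)
    rgb = np.empty((len(t_frames), 3))
    rgb[lvl_f == 0] = low_level
    rgb[lvl_f == 1] = white_level
    rgb[lvl_f == 2] = (0.0, green_level, 0.0)
    if corrupt:
        for stream, a, d in corrupt:
            if stream == "video":
                m = (t_frames >= a) & (t_frames < a + d) & (lvl_f != 2)
                rgb[m] = np.where(rgb[m] > (low_level + white_level) / 2,
                                  low_level, white_level)
    rgb = np.clip(rgb + rng.normal(0.0, video_noise, rgb.shape), 0.0, 1.0)
    frames = FrameStats(t_frames, rgb)

    bit1 = np.asarray([t + sync_codec.TEMPLATE_ONSET_OFFSET for _, t in spec.codes])
    return SynthSyncStreams(lux=lux, frames=frames,
                            lux_onsets=bit1, video_onsets=bit1)


# ---------------------------------------------------------------------------
# acceleration


def synth_accel(
    spec: SynthSpec,
    noise_sd: float = 0.01,
    n_bursts: int = 0,
    outlier_times: list | None = None,
    outlier_value: float = 3.0,
) -> SynthAccel:
    """Gravity baseline plus seeded motion, flat dropouts and spike outliers.

    Flat dropouts (``spec.dropout_intervals``) hold the last value so the
    moving SD is exactly zero; outliers are +/-``outlier_value`` g spikes
    at the requested times (seconds).
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = int(spec.duration * spec.acc_rate)
    t = np.arange(n) / spec.acc_rate
    xyz = np.tile([0.0, 0.0, 1.0], (n, 1))
    if noise_sd > 0:
        xyz += rng.normal(0.0, noise_sd, (n, 3))
    for _ in range(n_bursts):
        c = rng.uniform(0, spec.duration)
        width = rng.uniform(0.5, 2.0)
        amp = rng.uniform(0.2, 0.8, 3)
        env = np.exp(-0.5 * ((t - c) / width) ** 2)
        xyz += np.outer(env * np.sin(2 * np.pi * rng.uniform(1, 4) * t), amp)

    dropout = np.zeros(n, dtype=bool)
    for a, b in spec.dropout_intervals:
        m = (t >= a) & (t < b)
        if m.any():
            first = np.flatnonzero(m)[0]
            xyz[m] = xyz[first]
            dropout |= m

    outlier = np.zeros(n, dtype=bool)
    for ot in outlier_times or []:
        i = int(round(ot * spec.acc_rate))
        if 0 <= i < n and not dropout[i]:
            axis = int(rng.integers(0, 3))
            xyz[i, axis] = outlier_value * (1 if rng.random() < 0.5 else -1)
            outlier[i] = True

    return SynthAccel(series=AccelSeries(t, xyz), dropout_mask=dropout,
                      outlier_mask=outlier)


# ---------------------------------------------------------------------------
# video QC inputs


def synth_qc_inputs(
    spec: SynthSpec,
    dark_intervals: list | None = None,
    bright_level: float = 0.45,
    dark_level: float = 0.05,
    quiet_segment_counts: list | None = None,
    frame_shape: tuple = (64, 64),
    inverted_fraction: float = 0.0,
    n_prob_frames: int = 60,
) -> SynthQCInputs:
    """Ground-truthed inputs for the video quality-control rules.

    ``quiet_segment_counts`` lists, per synthetic flow field, how many of
    the 20 border segments should be quiet (|flow| about 0.5 px) while
    the rest move at 5 px. ``inverted_fraction`` of the probability
    sequence is drawn near 0.9, the rest near 0.1.
    """
    from egosync.timebase import UniformSignal
    from egosync.video_qc import border_segments

    rng = np.random.default_rng(spec.seed + 3)
    n = int(spec.duration)  # 1 fps sampling
    t = np.arange(n)
    intensity = np.full(n, bright_level) + rng.normal(0, 0.01, n)
    truth_intervals = []
    for a, b in dark_intervals or []:
        m = (t >= a) & (t < b)
        intensity[m] = dark_level
        if m.any():
            truth_intervals.append((float(t[m][0]), float(t[m][-1] + 1), "dark"))
    sig = UniformSignal(np.clip(intensity, 0, 1), rate=1.0, start_time=0.0)

    flows, static_truth = [], []
    h, w = frame_shape
    segs = border_segments(h, w, border=5, n_segments=20)
    for quiet_n in quiet_segment_counts or []:
        field_uv = np.full((h, w, 2), 5.0 / np.sqrt(2.0))
        order = rng.permutation(20)[:quiet_n]
        for s in order:
            rows, cols = segs[s]
            field_uv[rows, cols] = 0.5 / np.sqrt(2.0)
        flows.append(field_uv)
        static_truth.append(quiet_n >= 5)

    n_inv = int(round(inverted_fraction * n_prob_frames))
    probs = np.concatenate([
        np.clip(rng.normal(0.9, 0.03, n_inv), 0.55, 1.0),
        np.clip(rng.normal(0.1, 0.03, n_prob_frames - n_inv), 0.0, 0.45),
    ])
    probs = rng.permutation(probs)
    return SynthQCInputs(intensity=sig, dark_intervals=truth_intervals,
                         flows=flows, static_truth=static_truth,
                         inversion_probs=probs,
                         inverted_fraction=n_inv / max(n_prob_frames, 1))
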