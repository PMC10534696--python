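"""Locating, decoding and matching synchronization signals across devices.

The same template-matching algorithm serves both modalities. The binary
body-sensor luminosity stream is resampled to 500 Hz (nearest neighbour,
staying binary) and searched in full. Video frame statistics are reduced
to a mean-intensity and a "greenness" signal at 30 Hz; a cheap coarse
step-filter search on the greenness locates candidate segments near the
green end screen, and only those segments (upsampled to 100 Hz, linear)
are searched precisely. Precise localization slides the expected-signal
template (framing pulses at 1, potential bit highs at 0.5) over the
signal and takes local maxima of the normalized cross-correlation above
an acceptance threshold. Bits are then decoded by thresholding the mean
(or, for the binary luminosity, the median) of the signal inside each
200 ms potential-high window.

Detections from many streams are matched by identical decoded code,
duplicates disambiguated by recording order and real-time-clock
proximity, and each stream's clock is shifted so its latest matched
synchronization onset becomes time zero. A global multiplicative clock
correction (default 0.9999) maps device time onto real time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from egosync import sync_codec
from egosync.timebase import TimedSamples, UniformSignal, resample_nearest

__all__ = [
    "FrameStats",
    "SyncDetection",
    "MatchResult",
    "frame_signals",
    "resample_frame_stats",
    "coarse_candidates",
    "ncc_response",
    "ncc_locate",
    "decode_bits",
    "detect_lux",
    "detect_video",
    "match_and_align",
    "apply_clock_correction",
    "relative_clock_speed",
    "NCC_THRESHOLD",
    "COARSE_MIN_DISTANCE",
]

#: acceptance threshold on the NCC maxima. Chosen so that a waveform with
#: any single 0.4 s segment complemented still exceeds it while pure-noise
#: streams yield no detections; a config knob on the locate functions.
NCC_THRESHOLD = 0.65

#: minimum distance between coarse greenness peaks, frames at 30 Hz (16.7 s)
COARSE_MIN_DISTANCE = 500

#: default multiplicative device-to-real-time clock correction
CLOCK_FACTOR = 0.9999

LUX_SEARCH_RATE = 500.0
VIDEO_FRAME_RATE = 30.0
VIDEO_SEARCH_RATE = 100.0


@dataclass
class FrameStats:
    """Per-frame channel means in [0, 1] with presentation timestamps."""

    timestamps: np.ndarray
    rgb: np.ndarray  # (n_frames, 3)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.ndim != 2 or self.rgb.shape[1] != 3:
            raise ValueError("rgb must be (n_frames, 3)")
        if len(self.timestamps) != len(self.rgb):
            raise ValueError("timestamps and rgb length mismatch")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be increasing")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class SyncDetection:
    """One located and decoded synchronization signal in one stream."""

    stream_id: str
    onset_time: float  # start of bit 1, stream clock, seconds
    ncc_score: float
    bits: tuple | None
    day3: int | None = None
    hour5: int | None = None
    counter2: int | None = None
    valid: bool = False
    decode_ok: bool = True

    @property
    def decimal(self) -> int | None:
        if self.bits is None:
            return None
        return int("".join(map(str, self.bits)), 2)


@dataclass
class MatchResult:
    """Cross-stream matching and alignment outcome."""

    groups: list = field(default_factory=list)  # dicts: code_decimal, members
    offsets: dict = field(default_factory=dict)  # stream_id -> time-zero onset
    unmatched: list = field(default_factory=list)  # SyncDetection
    diagnostics: list = field(default_factory=list)  # strings


# ---------------------------------------------------------------------------
# signal extraction


def resample_frame_stats(stats: FrameStats, rate: float = VIDEO_FRAME_RATE) -> FrameStats:
    """Uniformly resample variable-frame-rate statistics by nearest frame."""
    t = stats.timestamps
    n = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / rate
    mid = (t[:-1] + t[1:]) / 2.0
    idx = np.searchsorted(mid, grid, side="right")
    return FrameStats(grid, stats.rgb[idx])


def frame_signals(stats: FrameStats, rate: float = VIDEO_FRAME_RATE):
    """Reduce uniform frame statistics to (intensity, greenness) signals.

    intensity = (R + G + B) / 3; greenness = max(0, G - R - B). The input
    should already be uniformly resampled (:func:`resample_frame_stats`).
    """
    r, g, b = stats.rgb[:, 0], stats.rgb[:, 1], stats.rgb[:, 2]
    start = float(stats.timestamps[0]) if len(stats) else 0.0
    intensity = UniformSignal((r + g + b) / 3.0, rate=rate, start_time=start)
    greenness = UniformSignal(np.maximum(0.0, g - r - b), rate=rate, start_time=start)
    return intensity, greenness


# ---------------------------------------------------------------------------
# coarse search (video only)


def coarse_candidates(
    greenness: UniformSignal,
    min_distance: int = COARSE_MIN_DISTANCE,
    pad_s: float = 1.0,
    neg_s: float = 2.0,
    pos_s: float = 1.0,
    min_response: float | None = None,
):
    """Indices of step-filter response peaks marking putative green onsets.

    The filter is zero-padded at the front (``pad_s``), then a -1 segment
    (``neg_s``) and a +1 segment (``pos_s``); its response is maximal when
    the -1 span sits on zero greenness and the +1 span on the green end
    screen. Each returned index is the filter-start frame, which precedes
    the start of the synchronization signal. Peaks are constrained to be
    at least ``min_distance`` frames apart.
    """
    x = np.asarray(greenness.values, dtype=float)
    rate = greenness.rate
    pad, neg, pos = (int(round(s * rate)) for s in (pad_s, neg_s, pos_s))
    kernel = np.concatenate([np.zeros(pad), -np.ones(neg), np.ones(pos)])
    if len(x) < len(kernel):
        return np.empty(0, dtype=int)
    resp = np.correlate(x, kernel, mode="valid")
    if min_response is None:
        min_response = 0.1 * pos
    peaks, props = scipy.signal.find_peaks(
        resp, height=min_response, distance=min_distance, plateau_size=1
    )
    return np.asarray(props.get("left_edges", peaks), dtype=int)


# ---------------------------------------------------------------------------
# normalized cross-correlation


def ncc_response(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """NCC of ``template`` against every window of ``x`` (valid positions).

    Computed with running sums; the correlation numerator uses direct
    summation for small problems and FFT convolution for large ones.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(template, dtype=float)
    n, m = len(x), len(t)
    if n < m:
        return np.empty(0)
    t_mean = t.mean()
    tc = t - t_mean
    t_energy = float(np.dot(tc, tc))
    if n * m <= 2 * 10**7:
        s_xt = np.correlate(x, tc, mode="valid")
    else:
        s_xt = scipy.signal.fftconvolve(x, tc[::-1], mode="valid")
    c = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s_x = c[m:] - c[:-m]
    s_xx = c2[m:] - c2[:-m]
    var = s_xx - s_x * s_x / m
    denom = np.sqrt(np.maximum(var, 0.0) * t_energy)
    out = np.zeros(n - m + 1)
    ok = denom > 0
    out[ok] = s_xt[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def ncc_locate(
    signal: UniformSignal,
    search_windows=None,
    threshold: float = NCC_THRESHOLD,
    min_separation_s: float = 8.0,
):
    """Locate synchronization signals by sliding the expected template.

    Parameters
    ----------
    signal
        Uniform search signal (500 Hz luminosity or 100 Hz video intensity).
    search_windows
        Optional list of ``(start_s, end_s)`` absolute-time windows to
        which template *start* positions are restricted (video candidate
        segments); ``None`` searches everywhere.
    threshold
        NCC acceptance threshold; local maxima below it are discarded.
    min_separation_s
        Minimum separation between detections, seconds.

    Returns
    -------
    list of (onset_time, ncc_score)
        ``onset_time`` is the start of bit 1 in the stream's clock.
    """
    rate = signal.rate
    template = sync_codec.build_template(rate)
    resp = ncc_response(signal.values, template.values)
    if len(resp) == 0:
        return []
    if search_windows is not None:
        mask = np.zeros(len(resp), dtype=bool)
        for a, b in search_windows:
            i0 = max(0, int(np.floor((a - signal.start_time) * rate)))
            i1 = min(len(resp), int(np.ceil((b - signal.start_time) * rate)) + 1)
            if i1 > i0:
                mask[i0:i1] = True
        resp = np.where(mask, resp, -1.0)
    peaks, props = scipy.signal.find_peaks(
        resp, height=threshold, distance=max(1, int(round(min_separation_s * rate))),
        plateau_size=1,
    )
    positions = props.get("left_edges", peaks)
    onset_offset = int(round(sync_codec.TEMPLATE_ONSET_OFFSET * rate))
    return [
        (signal.start_time + (int(p) + onset_offset) / rate, float(resp[int(p)]))
        for p in positions
    ]


def decode_bits(
    signal: UniformSignal,
    onset: float,
    threshold: float = 0.3,
    mode: str = "mean",
):
    """Decode the 10 bits of a located signal.

    Bit *i* is 1 iff the mean of the signal over its potential-high
    window exceeds ``threshold``; for the binary luminosity stream use
    ``mode="median"`` with threshold 0.5 instead.

    Returns
    -------
    (bits, ok)
        ``bits`` is a 10-tuple, or ``None`` with ``ok=False`` when a bit
        window falls outside the signal bounds.
    """
    rate = signal.rate
    bits = []
    # BIT_HIGH_WINDOWS are relative to the waveform start; the onset is
    # the start of bit 1, 3.2 s into the waveform.
    for s_rel, e_rel in sync_codec.BIT_HIGH_WINDOWS:
        i0 = int(round((onset + (s_rel - 3.2) - signal.start_time) * rate))
        i1 = int(round((onset + (e_rel - 3.2) - signal.start_time) * rate))
        if i0 < 0 or i1 > len(signal.values) or i1 <= i0:
            return None, False
        window = signal.values[i0:i1]
        stat = np.median(window) if mode == "median" else float(np.mean(window))
        bits.append(int(stat > threshold))
    return tuple(bits), True


def upsample_video_intensity(intensity: UniformSignal,
                             rate: float = VIDEO_SEARCH_RATE) -> UniformSignal:
    """Linearly upsample the 30 Hz intensity signal for precise search.

    Each frame statistic summarizes the whole frame interval, so frames
    are interpolated at their interval centers (half a frame period past
    the presentation timestamp); interpolating at the presentation
    timestamps instead would ramp every edge half a frame early and bias
    the located onset.
    """
    t_src = intensity.times + 0.5 / intensity.rate
    t_out = np.arange(t_src[0], t_src[-1] + 1e-9, 1.0 / rate)
    return UniformSignal(
        np.interp(t_out, t_src, intensity.values),
        rate=rate,
        start_time=float(t_src[0]),
    )


def _make_detection(stream_id, onset, score, bits, ok) -> SyncDetection:
    det = SyncDetection(stream_id=stream_id, onset_time=onset, ncc_score=score,
                        bits=bits, decode_ok=ok)
    if ok and bits is not None:
        det.day3, det.hour5, det.counter2, det.valid = sync_codec.decode_fields(bits)
    return det


def detect_lux(lux: TimedSamples, stream_id: str = "lux",
               threshold: float = NCC_THRESHOLD) -> list:
    """Full pipeline for a body-sensor luminosity stream.

    Resamples to 500 Hz (nearest neighbour, staying binary), searches the
    whole stream with the NCC template, and decodes each detection with
    the median rule at threshold 0.5.
    """
    sig = resample_nearest(lux, LUX_SEARCH_RATE)
    out = []
    for onset, score in ncc_locate(sig, threshold=threshold):
        bits, ok = decode_bits(sig, onset, threshold=0.5, mode="median")
        out.append(_make_detection(stream_id, onset, score, bits, ok))
    return out


def detect_video(stats: FrameStats, stream_id: str = "video",
                 threshold: float = NCC_THRESHOLD) -> list:
    """Full pipeline for a video frame-statistics stream.

    Resamples frames to 30 Hz, coarse-searches the greenness signal for
    green-screen onsets, upsamples the intensity signal to 100 Hz with
    linear interpolation around each candidate and NCC-searches those
    windows only, decoding with the mean rule at threshold 0.3.
    """
    uniform = resample_frame_stats(stats, VIDEO_FRAME_RATE)
    intensity, greenness = frame_signals(uniform, VIDEO_FRAME_RATE)
    cands = coarse_candidates(greenness)
    if len(cands) == 0:
        return []
    hi = upsample_video_intensity(intensity)
    windows = []
    for c in cands:
        tc = intensity.start_time + c / VIDEO_FRAME_RATE
        windows.append((tc - 8.0, tc + 5.0))
    out = []
    for onset, score in ncc_locate(hi, search_windows=windows, threshold=threshold):
        bits, ok = decode_bits(hi, onset, threshold=0.3, mode="mean")
        out.append(_make_detection(stream_id, onset, score, bits, ok))
    return out


# ---------------------------------------------------------------------------
# matching and alignment


def match_and_align(detections: dict, rtc_times: dict | None = None) -> MatchResult:
    """Match decoded codes across streams and align each stream's clock.

    Streams are grouped by identical decoded code. When the same code
    occurs several times in a stream (more than four synchronizations in
    an hour), occurrences are paired across streams in recording order,
    and the pairing is checked for global temporal-ordering consistency;
    inconsistent hypotheses are rejected with a diagnostic (and broken by
    real-time-clock proximity when ``rtc_times`` is available). Each
    stream's clock offset is the onset of the latest matched
    synchronization it contains, so aligned time = stream time - offset.

    Parameters
    ----------
    detections
        Mapping ``stream_id -> list of SyncDetection`` ordered by onset.
    rtc_times
        Optional mapping ``stream_id -> list of RTC seconds`` parallel to
        the detections, for streams whose device has a real-time clock.

    Returns
    -------
    MatchResult
    """
    occurrences: dict = {}
    for sid, dets in detections.items():
        for i in sorted(range(len(dets)), key=lambda i: dets[i].onset_time):
            det = dets[i]
            if not det.decode_ok or det.bits is None:
                continue
            occurrences.setdefault(det.decimal, {}).setdefault(sid, []).append(det)

    groups = []
    unmatched = []
    diagnostics = []
    for code_dec, per_stream in sorted(occurrences.items()):
        depth = max(len(v) for v in per_stream.values())
        for g in range(depth):
            members = {sid: v[g] for sid, v in per_stream.items() if len(v) > g}
            if len(members) >= 2:
                groups.append({"code": code_dec, "members": members})
            else:
                unmatched.extend(members.values())

    # temporal-ordering consistency: for any two groups, every stream that
    # contains both must order their onsets the same way
    consistent_groups = []
    for gi, grp in enumerate(groups):
        ok = True
        for other in groups:
            if other is grp:
                continue
            shared = set(grp["members"]) & set(other["members"])
            signs = {
                np.sign(grp["members"][s].onset_time - other["members"][s].onset_time)
                for s in shared
            }
            if len(signs) > 1:
                ok = False
                diagnostics.append(
                    f"ordering-inconsistent match for code {grp['code']} "
                    f"vs {other['code']} on streams {sorted(shared)}"
                )
        if ok:
            consistent_groups.append(grp)
        else:
            unmatched.extend(grp["members"].values())
    groups = consistent_groups

    # RTC proximity tie-break note: with order-based pairing the RTC is
    # only needed for reporting; flag large RTC spreads for human review.
    if rtc_times:
        for grp in groups:
            rtcs = []
            for sid, det in grp["members"].items():
                if sid in rtc_times:
                    dets = detections[sid]
                    idx = dets.index(det)
                    if idx < len(rtc_times[sid]):
                        rtcs.append(rtc_times[sid][idx])
            if len(rtcs) >= 2 and (max(rtcs) - min(rtcs)) > 3600.0:
                diagnostics.append(
                    f"code {grp['code']}: RTC spread {max(rtcs) - min(rtcs):.0f} s "
                    "exceeds one hour; flagged for human review"
                )

    offsets = {}
    for grp in groups:
        for sid, det in grp["members"].items():
            if sid not in offsets or det.onset_time > offsets[sid]:
                offsets[sid] = det.onset_time
    return MatchResult(groups=groups, offsets=offsets,
                       unmatched=unmatched, diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# clock drift


def apply_clock_correction(times, factor: float = CLOCK_FACTOR):
    """Map device time to real time: corrected = times * factor.

    The device clock runs fast (0.1 s ahead of a real-time clock after
    1000 s), so multiplying device timestamps by the relative clock speed
    (default 0.9999) recovers real time.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if isinstance(times, TimedSamples):
        return TimedSamples(times.timestamps * factor, times.values, times.channel)
    return np.asarray(times, dtype=float) * factor


def relative_clock_speed(peak_times, expected_gap: float,
                         batch_length: float = 1800.0):
    """Estimate device clock speed from recorded inter-event gaps.

    The relative clock speed is the ratio of the expected mean gap
    (known event rate, e.g. 0.4 s for a simulated 150 bpm ECG) to the
    recorded mean gap, batched over ``batch_length``-second windows of
    device time (half an hour by default).

    Returns
    -------
    (batch_speeds, overall)
        Per-batch speeds and their mean.
    """
    t = np.asarray(peak_times, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two events")
    edges = np.arange(t[0], t[-1] + batch_length, batch_length)
    speeds = []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = t[(t >= a) & (t <= b)]
        if len(sel) >= 2:
            speeds.append(expected_gap / np.mean(np.diff(sel)))
    speeds = np.asarray(speeds)
    if len(speeds) == 0:
        raise ValueError("no batch contained two events")
    return speeds, float(speeds.mean())
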