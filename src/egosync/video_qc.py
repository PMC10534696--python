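"""Video quality control: dark, static and inverted period labelling.

Unusable head-camera periods are labelled, not removed, so absolute
timestamps survive. Dark frames are those whose mean intensity
(normalized to [0, 1]) is below T = 0.15. Static scenes are decided from
dense optical flow between frame pairs sampled once per second: the
5-pixel image border is unrolled clockwise into a strip, split into 20
equal segments, and the scene is static when at least 5 segments have a
mean absolute flow magnitude under 2 pixels (camera motion moves the
whole border; dynamic objects rarely cover it). Whole-session inversion
is decided from per-frame inversion probabilities (1 fps): inverted
above an 80 % inverted-frame fraction, flagged for human review in the
0.20-0.80 band. Labels are exported as SRT subtitle cues so an operator
can see them during playback.

Flow fields and inversion probabilities come from pluggable providers;
a deterministic block-matching flow estimator and a top-versus-bottom
brightness heuristic ship as defaults for testing. Neural providers can
be adapted behind the same call signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabelTrack",
    "detect_dark",
    "static_decision",
    "classify_session_inversion",
    "write_srt",
    "read_srt",
    "block_matching_flow",
    "brightness_inversion_prob",
    "DARK_THRESHOLD",
]

DARK_THRESHOLD = 0.15


@dataclass
class LabelTrack:
    """Typed, half-open, sorted time intervals ``(start, end, label)``."""

    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            [(float(a), float(b), str(lab)) for a, b, lab in self.intervals]
        )
        for a, b, _ in self.intervals:
            if b < a or a < 0:
                raise ValueError(f"bad interval [{a}, {b})")
        by_label: dict = {}
        for a, b, lab in self.intervals:
            if lab in by_label and a < by_label[lab]:
                raise ValueError(f"overlapping {lab!r} intervals")
            by_label[lab] = max(b, by_label.get(lab, 0.0))

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelTrack) and self.intervals == other.intervals


# ---------------------------------------------------------------------------
# dark periods


def detect_dark(intensity, threshold: float = DARK_THRESHOLD, label: str = "dark") -> LabelTrack:
    """Label maximal runs of frames with mean intensity strictly below T.

    Frame ``k`` owns the half-open span ``[t_k, t_k + 1/rate)``, so the
    dark intervals and their complement partition the frame timeline
    exactly.
    """
    x = np.asarray(intensity.values, dtype=float)
    dark = x < threshold
    intervals = []
    for a, b in _bool_runs(dark):
        t0 = intensity.start_time + a / intensity.rate
        t1 = intensity.start_time + (b + 1) / intensity.rate
        intervals.append((t0, t1, label))
    return LabelTrack(intervals)


def _bool_runs(mask):
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1))
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        ends.append(len(m) - 1)
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# static periods


def border_segments(height: int, width: int, border: int = 5, n_segments: int = 20):
    """Index arrays of the 20 border segments of an H x W frame.

    The ``border``-pixel frame border is unrolled clockwise from the
    top-left corner -- top edge left to right, right edge top to bottom,
    bottom edge right to left, left edge bottom to top, each as a run of
    ``border``-deep cross-sections -- into one strip of pixels, which is
    split into ``n_segments`` contiguous equal-length segments (remainder
    pixels go to the last segment). Returns a list of ``(rows, cols)``
    integer index pairs, one per segment.
    """
    if height <= 2 * border or width <= 2 * border:
        raise ValueError("frame smaller than twice the border width")
    rows, cols = [], []
    for c in range(width):  # top, left -> right
        rows.extend(range(border))
        cols.extend([c] * border)
    for r in range(border, height - border):  # right, top -> bottom
        rows.extend([r] * border)
        cols.extend(range(width - border, width))
    for c in range(width - 1, -1, -1):  # bottom, right -> left
        rows.extend(range(height - border, height))
        cols.extend([c] * border)
    for r in range(height - border - 1, border - 1, -1):  # left, bottom -> top
        rows.extend([r] * border)
        cols.extend(range(border))
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    seg_len = len(rows) // n_segments
    out = []
    for s in range(n_segments):
        a = s * seg_len
        b = (s + 1) * seg_len if s < n_segments - 1 else len(rows)
        out.append((rows[a:b], cols[a:b]))
    return out


def static_decision(
    flow: np.ndarray,
    border: int = 5,
    n_segments: int = 20,
    mag_threshold: float = 2.0,
    min_quiet: int = 5,
) -> bool:
    """Decide whether a frame pair comes from a static camera.

    ``flow`` is an (H, W, 2) per-pixel displacement field in pixels.
    True iff at least ``min_quiet`` of the ``n_segments`` border segments
    have a mean absolute flow magnitude below ``mag_threshold``.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.ndim != 3 or flow.shape[2] != 2:
        raise ValueError("flow must be (H, W, 2)")
    if not np.isfinite(flow).all():
        raise ValueError("flow must be finite")
    mag = np.sqrt(flow[..., 0] ** 2 + flow[..., 1] ** 2)
    quiet = 0
    for rows, cols in border_segments(*mag.shape, border=border, n_segments=n_segments):
        if mag[rows, cols].mean() < mag_threshold:
            quiet += 1
    return quiet >= min_quiet


# ---------------------------------------------------------------------------
# inversion


def classify_session_inversion(
    probs,
    frac_threshold: float = 0.80,
    review_floor: float = 0.20,
) -> str:
    """Classify a session as normal / inverted / review.

    ``probs`` holds one inversion probability per sampled frame (1 fps);
    a frame counts as inverted when its probability exceeds 0.5. The
    session is ``"inverted"`` when the inverted fraction exceeds
    ``frac_threshold``, ``"review"`` when it is high but not conclusive
    (``review_floor`` up to ``frac_threshold``), else ``"normal"``.
    """
    probs = np.asarray(probs, dtype=float)
    if len(probs) == 0:
        warnings.warn("no sampled frames; tagging session for review", stacklevel=2)
        return "review"
    frac = float(np.mean(probs > 0.5))
    if frac > frac_threshold:
        return "inverted"
    if frac >= review_floor:
        return "review"
    return "normal"


# ---------------------------------------------------------------------------
# default providers


def block_matching_flow(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    block: int = 8,
    search: int = 4,
) -> np.ndarray:
    """Deterministic dense flow by exhaustive block matching.

    For each ``block`` x ``block`` tile of ``frame_a`` (grayscale, 2-D)
    the integer displacement within ``+/-search`` pixels minimizing the
    sum of absolute differences in ``frame_b`` is assigned to every pixel
    of the tile. Intended as the default testing provider, not as a
    competitive flow estimator.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("frames must be equal-shaped 2-D arrays")
    h, w = a.shape
    flow = np.zeros((h, w, 2))
    for r0 in range(0, h - block + 1, block):
        for c0 in range(0, w - block + 1, block):
            tile = a[r0:r0 + block, c0:c0 + block]
            best, best_dv = np.inf, (0, 0)
            for dr in range(-search, search + 1):
                for dc in range(-search, search + 1):
                    r1, c1 = r0 + dr, c0 + dc
                    if r1 < 0 or c1 < 0 or r1 + block > h or c1 + block > w:
                        continue
                    sad = np.abs(tile - b[r1:r1 + block, c1:c1 + block]).sum()
                    if sad < best - 1e-12:
                        best, best_dv = sad, (dc, dr)
            flow[r0:r0 + block, c0:c0 + block, 0] = best_dv[0]
            flow[r0:r0 + block, c0:c0 + block, 1] = best_dv[1]
    return flow


def brightness_inversion_prob(frame: np.ndarray) -> float:
    """Heuristic inversion probability: is the top brighter than the bottom?

    Indoor scenes are usually lit from above (ceilings and windows are
    bright, floors dark), so a frame whose top half is darker than its
    bottom half is likely inverted. Returns a probability in [0, 1].
    """
    f = np.asarray(frame, dtype=float)
    h = f.shape[0]
    top = f[: h // 2].mean()
    bottom = f[h - h // 2:].mean()
    # logistic squash of the normalized brightness difference
    return float(1.0 / (1.0 + np.exp(10.0 * (top - bottom) / max(top + bottom, 1e-9))))


# ---------------------------------------------------------------------------
# SRT export


def _fmt_srt_time(seconds: float) -> str:
    ms = int(round(seconds * 1000.0))
    h, rem = divmod(ms, 3_600_000)
    m, rem = divmod(rem, 60_000)
    s, ms = divmod(rem, 1000)
    return f"{h:02d}:{m:02d}:{s:02d},{ms:03d}"


def _parse_srt_time(text: str) -> float:
    hms, ms = text.strip().split(",")
    h, m, s = hms.split(":")
    total_ms = ((int(h) * 60 + int(m)) * 60 + int(s)) * 1000 + int(ms)
    return total_ms / 1000.0


def write_srt(track: LabelTrack, path) -> None:
    """Write a LabelTrack as a SubRip (.srt) file.

    Cues are 1-indexed and sorted by start time; times are rendered at
    millisecond resolution as ``HH:MM:SS,mmm``. An empty track yields an
    empty file.
    """
    lines = []
    for i, (a, b, lab) in enumerate(track.intervals, start=1):
        lines.append(f"{i}\n{_fmt_srt_time(a)} --> {_fmt_srt_time(b)}\n{lab}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def read_srt(path) -> LabelTrack:
    """Parse a SubRip file written by :func:`write_srt` back to a track."""
    with open(path, "r", encoding="utf-8") as fh:
        content = fh.read()
    intervals = []
    for cue in content.strip().split("\n\n"):
        if not cue.strip():
            continue
        rows = cue.strip().split("\n")
        times = rows[1]
        start_s, end_s = times.split("-->")
        label = "\n".join(rows[2:])
        intervals.append((_parse_srt_time(start_s), _parse_srt_time(end_s), label))
    return LabelTrack(intervals)
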