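"""Timed-signal containers, the sensor-log binary dialect and resampling.

The body sensor streams three channels -- ECG (~250 Hz), binary ambient
luminosity (~250 Hz) and triaxial acceleration (~65 Hz) -- none of which
is uniformly sampled in time. This module provides the nonuniform
(:class:`TimedSamples`) and uniform (:class:`UniformSignal`) containers
used throughout the package, a fully documented binary log dialect
(``.eg.dat``) emulating the device's 512-byte-block files, session
splitting/stitching for the 5-minute recording blocks, and
nearest-neighbour resampling onto a uniform grid.

Binary dialect (little-endian)
------------------------------
16-byte header: magic ``EGAC`` (4 bytes), version ``u16`` (=1), nominal
ECG rate ``u16`` (Hz), nominal ACC rate ``u16`` (Hz), 6 reserved bytes.
The payload is a sequence of 512-byte blocks containing tagged records
in chronological order; a record that does not fit in the remainder of a
block is deferred to the next block and the remainder is zero-padded
(tag 0 = padding). Timestamps are ``u32`` ticks at 1 ms resolution.

==== ======================= ==========================================
tag  layout                  payload
==== ======================= ==========================================
1    ``<B I i``  (9 bytes)   ECG sample, value = mV * 1000 (``i32``)
2    ``<B I iii`` (17 bytes) ACC sample, per-axis value = g * 1e6
3    ``<B I B``  (6 bytes)   LUX sample, value in {0, 1}
==== ======================= ==========================================
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TimedSamples",
    "UniformSignal",
    "SessionBlockSet",
    "SensorLogFormatError",
    "read_sensor_log",
    "write_sensor_log",
    "split_restore_blocks",
    "resample_nearest",
]

BLOCK_SIZE = 512
MAGIC = b"EGAC"
VERSION = 1
_HEADER = struct.Struct("<4sHHH6x")
_REC_ECG = struct.Struct("<BIi")
_REC_ACC = struct.Struct("<BIiii")
_REC_LUX = struct.Struct("<BIB")
_TAG_PAD, _TAG_ECG, _TAG_ACC, _TAG_LUX = 0, 1, 2, 3

#: nominal block length of one on-device recording file, seconds
NOMINAL_BLOCK_LENGTH = 300.0


class SensorLogFormatError(ValueError):
    """Raised for a bad magic number or unsupported dialect version."""


@dataclass
class TimedSamples:
    """Nonuniformly sampled channel data.

    Parameters
    ----------
    timestamps
        Seconds since device power-on, strictly increasing.
    values
        Per-sample scalar (ecg/lux) or 3-vector (acc).
    channel
        One of ``{"ecg", "lux", "acc"}``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.channel not in ("ecg", "lux", "acc"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.timestamps.ndim != 1:
            raise ValueError("timestamps must be 1-D")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values length mismatch")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.channel == "lux" and self.values.size and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("lux values must be binary")
        if self.channel == "acc":
            if self.values.ndim != 2 or self.values.shape[1] != 3:
                raise ValueError("acc values must be (n, 3)")
            if self.values.size and not np.isfinite(self.values).all():
                raise ValueError("acc values must be finite")

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_csv(self, path) -> None:
        """Export as a ``timestamp,value`` (or ``timestamp,x,y,z``) CSV."""
        if self.channel == "acc":
            df = pd.DataFrame(
                {"timestamp": self.timestamps,
                 "x": self.values[:, 0], "y": self.values[:, 1], "z": self.values[:, 2]}
            )
        else:
            df = pd.DataFrame({"timestamp": self.timestamps, "value": self.values})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, channel: str) -> "TimedSamples":
        df = pd.read_csv(path)
        if channel == "acc":
            values = df[["x", "y", "z"]].to_numpy()
        else:
            values = df["value"].to_numpy()
        return cls(df["timestamp"].to_numpy(), values, channel)


@dataclass
class UniformSignal:
    """Uniformly sampled signal: sample ``k`` maps to ``start_time + k/rate``."""

    values: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.values)) / self.rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate


@dataclass
class SessionBlockSet:
    """Ordered recording blocks (nominally 5 minutes each) of one device."""

    blocks: list = field(default_factory=list)  # (block_start_time, TimedSamples)
    nominal_block_length: float = NOMINAL_BLOCK_LENGTH

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.blocks]
        if any(b > a for a, b in zip(starts[1:], starts)):
            raise ValueError("blocks must be ordered by start time")


# ---------------------------------------------------------------------------
# binary sensor-log dialect


def write_sensor_log(path, ecg: TimedSamples, lux: TimedSamples, acc: TimedSamples) -> None:
    """Write three channels to the ``.eg.dat`` dialect described above.

    Records from all channels are merged in (tick, tag) order and packed
    into 512-byte blocks, so the writer is deterministic and the
    write -> read -> write round trip is byte-identical.
    """
    recs = []
    for t, v in zip(ecg.timestamps, ecg.values):
        tick = int(round(t * 1000.0))
        recs.append((tick, _TAG_ECG, _REC_ECG.pack(_TAG_ECG, tick, int(round(v * 1000.0)))))
    for t, (x, y, z) in zip(acc.timestamps, acc.values):
        tick = int(round(t * 1000.0))
        recs.append((tick, _TAG_ACC, _REC_ACC.pack(
            _TAG_ACC, tick, int(round(x * 1e6)), int(round(y * 1e6)), int(round(z * 1e6)))))
    for t, v in zip(lux.timestamps, lux.values):
        tick = int(round(t * 1000.0))
        recs.append((tick, _TAG_LUX, _REC_LUX.pack(_TAG_LUX, tick, int(v))))
    recs.sort(key=lambda r: (r[0], r[1]))

    out = bytearray(_HEADER.pack(MAGIC, VERSION, 250, 65))
    block = bytearray()
    for _, _, payload in recs:
        if len(block) + len(payload) > BLOCK_SIZE:
            block.extend(b"\0" * (BLOCK_SIZE - len(block)))
            out.extend(block)
            block = bytearray()
        block.extend(payload)
    if block:
        block.extend(b"\0" * (BLOCK_SIZE - len(block)))
        out.extend(block)
    with open(path, "wb") as fh:
        fh.write(bytes(out))


def read_sensor_log(path):
    """Read a ``.eg.dat`` file into (ecg, lux, acc) :class:`TimedSamples`.

    A truncated final block is dropped with a warning; all whole blocks
    are recovered. ACC values are clipped to the sensor's +/-2 g range.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size:
        raise SensorLogFormatError("file shorter than header")
    magic, version, _ecg_rate, _acc_rate = _HEADER.unpack_from(raw, 0)
    if magic != MAGIC:
        raise SensorLogFormatError(f"bad magic {magic!r}")
    if version != VERSION:
        raise SensorLogFormatError(f"unsupported version {version}")

    payload = raw[_HEADER.size:]
    n_blocks, leftover = divmod(len(payload), BLOCK_SIZE)
    if leftover:
        warnings.warn(
            f"truncated final block ({leftover} bytes) dropped; "
            f"{n_blocks} whole blocks recovered",
            stacklevel=2,
        )
    ecg_t, ecg_v, lux_t, lux_v, acc_t, acc_v = [], [], [], [], [], []
    for b in range(n_blocks):
        off = b * BLOCK_SIZE
        end = off + BLOCK_SIZE
        while off < end:
            tag = payload[off]
            if tag == _TAG_PAD:
                break
            if tag == _TAG_ECG and off + _REC_ECG.size <= end:
                _, tick, v = _REC_ECG.unpack_from(payload, off)
                ecg_t.append(tick / 1000.0)
                ecg_v.append(v / 1000.0)
                off += _REC_ECG.size
            elif tag == _TAG_ACC and off + _REC_ACC.size <= end:
                _, tick, x, y, z = _REC_ACC.unpack_from(payload, off)
                acc_t.append(tick / 1000.0)
                acc_v.append((x / 1e6, y / 1e6, z / 1e6))
                off += _REC_ACC.size
            elif tag == _TAG_LUX and off + _REC_LUX.size <= end:
                _, tick, v = _REC_LUX.unpack_from(payload, off)
                lux_t.append(tick / 1000.0)
                lux_v.append(float(v))
                off += _REC_LUX.size
            else:
                raise SensorLogFormatError(f"bad record tag {tag} at offset {off}")
    acc_arr = np.clip(np.asarray(acc_v, dtype=float).reshape(-1, 3), -2.0, 2.0)
    return (
        TimedSamples(np.asarray(ecg_t), np.asarray(ecg_v), "ecg"),
        TimedSamples(np.asarray(lux_t), np.asarray(lux_v), "lux"),
        TimedSamples(np.asarray(acc_t), acc_arr, "acc"),
    )


# ---------------------------------------------------------------------------
# session splitting


def split_restore_blocks(blocks, gap_threshold: float = 1.0):
    """Split ordered recording blocks into sessions at large timestamp gaps.

    Device files are written in nominal 5-minute blocks; a power cycle or
    pause shows up as a large gap (or a timestamp reset) *inside* the
    concatenated sample stream. Every internal gap larger than
    ``gap_threshold`` seconds, or any non-increasing step, starts a new
    session; the head of a partial block preceding the gap is restored to
    the end of the previous session. Concatenating the returned sessions
    in order reproduces the input sample sequence exactly.

    Parameters
    ----------
    blocks
        :class:`SessionBlockSet` or list of ``(start_time, TimedSamples)``.
    gap_threshold
        Seconds; gaps strictly larger than this split sessions.

    Returns
    -------
    list of TimedSamples
        One concatenated stream per session.
    """
    if isinstance(blocks, SessionBlockSet):
        blocks = blocks.blocks
    if not blocks:
        return []
    channel = blocks[0][1].channel
    ts = np.concatenate([b.timestamps for _, b in blocks])
    vs = np.concatenate([b.values for _, b in blocks])
    if len(ts) == 0:
        return []
    dt = np.diff(ts)
    cuts = np.flatnonzero((dt > gap_threshold) | (dt <= 0)) + 1
    sessions = []
    for seg_t, seg_v in zip(np.split(ts, cuts), np.split(vs, cuts)):
        sessions.append(TimedSamples(seg_t, seg_v, channel))
    return sessions


# ---------------------------------------------------------------------------
# resampling


def resample_nearest(x, rate: float) -> UniformSignal:
    """Resample nonuniform samples onto a uniform grid by nearest neighbour.

    The grid spans ``[first, last]`` input timestamp at the requested
    rate. Output values are drawn only from input values, so a binary
    stream stays binary. A grid point exactly halfway between two input
    samples takes the later sample.

    Parameters
    ----------
    x
        :class:`TimedSamples` (or any object with ``timestamps``/``values``).
    rate
        Target rate in Hz, > 0.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    t = np.asarray(x.timestamps, dtype=float)
    v = np.asarray(x.values, dtype=float)
    if len(t) == 0:
        raise ValueError("need at least one sample")
    n = int(np.floor((t[-1] - t[0]) * rate + 1e-9)) + 1
    grid = t[0] + np.arange(n) / rate
    mid = (t[:-1] + t[1:]) / 2.0
    idx = np.searchsorted(mid, grid, side="right")
    return UniformSignal(v[idx], rate=rate, start_time=t[0])
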