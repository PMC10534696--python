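"""Construction and rendering of the 10-bit coded-light synchronization code.

A synchronization event broadcast from the base-unit screen encodes the
current date and time into 10 bits: 3 bits for the day of the month
modulo 8, 5 bits for the hour (0-23) and a 2-bit counter of
synchronizations started within the hour. The code is played back as a
piecewise-constant intensity waveform:

* 2000 ms low preamble, then high/low/high framing pulses (400 ms each);
* ten 400 ms bit periods -- an "on" bit is a 200 ms high pulse followed
  by 200 ms low, an "off" bit is 400 ms low;
* low/high/low/high framing postamble (400 ms each);
* a 1000 ms full-green end screen (R = B = 0, G = 255).

The total duration is 9800 ms for every code. Fields are packed
MSB-first, day then hour then counter; bit *i* (1-based) can be high
during the window starting ``3200 + 400*(i-1)`` ms into the waveform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from egosync.timebase import UniformSignal

__all__ = [
    "SyncCode",
    "SyncWaveform",
    "make_code",
    "decode_fields",
    "build_waveform",
    "build_template",
    "enumerate_codes",
    "BIT_HIGH_WINDOWS",
    "TOTAL_DURATION",
    "TEMPLATE_DURATION",
    "TEMPLATE_ONSET_OFFSET",
    "GREEN_INTENSITY",
]

#: total waveform duration, seconds
TOTAL_DURATION = 9.8
#: template (preamble..postamble, green excluded) duration, seconds
TEMPLATE_DURATION = 8.8
#: seconds from template start to the start of bit 1
TEMPLATE_ONSET_OFFSET = 3.2
#: intensity-channel value of the green end screen: mean of (0, 255, 0)/255
GREEN_INTENSITY = 1.0 / 3.0

#: [s_i, e_i) potential-high window of bit i (1-based), seconds from waveform start
BIT_HIGH_WINDOWS = [(3.2 + 0.4 * i, 3.2 + 0.4 * i + 0.2) for i in range(10)]


@dataclass(frozen=True)
class SyncCode:
    """A 10-bit synchronization code and its decoded fields."""

    bits: tuple  # ten ints in {0, 1}
    day3: int
    hour5: int
    counter2: int

    @property
    def valid(self) -> bool:
        """False for bit patterns whose hour field exceeds 23."""
        return self.hour5 <= 23

    @property
    def decimal(self) -> int:
        """Decimal value of the bit string (for easy matching)."""
        return int("".join(map(str, self.bits)), 2)

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


@dataclass(frozen=True)
class SyncWaveform:
    """Ordered (duration_s, level) segments; level in {'low','high','green'}."""

    segments: tuple

    @property
    def duration(self) -> float:
        return sum(d for d, _ in self.segments)


def _pack(value: int, width: int):
    return tuple((value >> (width - 1 - k)) & 1 for k in range(width))


def make_code(day_of_month: int, hour: int, counter: int) -> SyncCode:
    """Build the code for a synchronization started at a given date/time.

    Parameters
    ----------
    day_of_month : 1-31
    hour : 0-23
    counter : 0-3, number of synchronizations already started this hour.
    """
    if not 1 <= day_of_month <= 31:
        raise ValueError("day_of_month must be in 1..31")
    if not 0 <= hour <= 23:
        raise ValueError("hour must be in 0..23")
    if not 0 <= counter <= 3:
        raise ValueError("counter must be in 0..3")
    day3 = day_of_month % 8
    bits = _pack(day3, 3) + _pack(hour, 5) + _pack(counter, 2)
    return SyncCode(bits=bits, day3=day3, hour5=hour, counter2=counter)


def decode_fields(bits):
    """Unpack 10 bits into (day3, hour5, counter2, valid).

    Any bit pattern is accepted; ``valid`` is False when the hour field
    decodes to a value above 23 (impossible from a real clock).
    """
    bits = tuple(int(b) for b in bits)
    if len(bits) != 10 or any(b not in (0, 1) for b in bits):
        raise ValueError("need exactly 10 bits in {0,1}")

    def unpack(bs):
        v = 0
        for b in bs:
            v = (v << 1) | b
        return v

    day3, hour5, counter2 = unpack(bits[:3]), unpack(bits[3:8]), unpack(bits[8:])
    return day3, hour5, counter2, hour5 <= 23


def code_from_bits(bits) -> SyncCode:
    """Wrap raw bits in a :class:`SyncCode` (validity via ``.valid``)."""
    day3, hour5, counter2, _ = decode_fields(bits)
    return SyncCode(bits=tuple(int(b) for b in bits), day3=day3, hour5=hour5, counter2=counter2)


def waveform_segments(code: SyncCode) -> SyncWaveform:
    """The piecewise-constant segment list for one code."""
    segs = [(2.0, "low"), (0.4, "high"), (0.4, "low"), (0.4, "high")]
    for b in code.bits:
        if b:
            segs += [(0.2, "high"), (0.2, "low")]
        else:
            segs.append((0.4, "low"))
    segs += [(0.4, "low"), (0.4, "high"), (0.4, "low"), (0.4, "high"), (1.0, "green")]
    return SyncWaveform(segments=tuple(segs))


def waveform_level(code: SyncCode, t):
    """Segment level of the waveform at time(s) ``t`` (seconds from start).

    Returns an integer array: 0 = low, 1 = high, 2 = green. Times outside
    [0, 9.8) are low.
    """
    wf = waveform_segments(code)
    # exact integer-millisecond edges avoid cumulative float drift
    edges_ms = np.cumsum([0] + [int(round(d * 1000)) for d, _ in wf.segments])
    codes = np.array([{"low": 0, "high": 1, "green": 2}[lvl] for _, lvl in wf.segments])
    t_ms = np.asarray(t, dtype=float) * 1000.0
    idx = np.searchsorted(edges_ms, t_ms + 1e-6, side="right") - 1
    out = np.zeros(t_ms.shape, dtype=int)
    inside = (idx >= 0) & (idx < len(codes)) & (t_ms + 1e-6 < edges_ms[-1]) & (t_ms >= -1e-6)
    out[inside] = codes[idx[inside]]
    return out


def build_waveform(code: SyncCode, rate: float, channel: str = "intensity") -> UniformSignal:
    """Sample the waveform for ``code`` on a uniform grid.

    ``channel="intensity"`` maps high -> 1.0, low -> 0.0 and the green
    screen to its channel-mean intensity 1/3; ``channel="greenness"`` is
    1.0 during the green segment and 0 elsewhere.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if channel not in ("intensity", "greenness"):
        raise ValueError("channel must be 'intensity' or 'greenness'")
    n = int(round(TOTAL_DURATION * rate))
    lvl = waveform_level(code, np.arange(n) / rate)
    if channel == "intensity":
        values = np.choose(lvl, [0.0, 1.0, GREEN_INTENSITY])
    else:
        values = (lvl == 2).astype(float)
    return UniformSignal(values, rate=rate, start_time=0.0)


def build_template(rate: float) -> UniformSignal:
    """The expected-signal template used for normalized cross-correlation.

    Covers preamble through postamble (8.8 s), with framing pulses at 1.0
    and every potential bit-high window at 0.5 -- the average over all
    1024 possible codes. The green screen is excluded.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    n = int(round(TEMPLATE_DURATION * rate))
    t = np.arange(n) / rate
    values = np.zeros(n)
    for a, b in [(2.0, 2.4), (2.8, 3.2), (7.6, 8.0), (8.4, 8.8)]:
        values[(t >= a) & (t < b)] = 1.0
    for a, b in BIT_HIGH_WINDOWS:
        values[(t >= a) & (t < b)] = 0.5
    return UniformSignal(values, rate=rate, start_time=0.0)


def enumerate_codes():
    """All 2**10 = 1024 codes in lexicographic bit order."""
    out = []
    for v in range(1024):
        bits = tuple((v >> (9 - k)) & 1 for k in range(10))
        out.append(code_from_bits(bits))
    return out
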