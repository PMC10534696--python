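"""Triaxial accelerometer cleaning and resultant magnitude.

Sensor dropouts show up as perfectly flat stretches: samples whose
5-point moving standard deviation falls below 0.001 g on any axis are
masked invalid, together with the 5 samples on each side. The extreme
0.05 % tails of each axis are then masked as potential outliers, and the
three axes are combined into a single resultant magnitude
``sqrt(x^2 + y^2 + z^2)``. Masking never modifies sample values, only
the validity mask, so the raw data are preserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AccelSeries", "remove_dropouts", "trim_outliers", "resultant"]


@dataclass
class AccelSeries:
    """Triaxial acceleration in g with a per-sample validity mask."""

    t: np.ndarray
    xyz: np.ndarray  # (n, 3), g
    valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (n, 3)")
        if self.valid is None:
            self.valid = np.ones(len(self.t), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.xyz) == len(self.valid)):
            raise ValueError("length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def copy(self) -> "AccelSeries":
        return AccelSeries(self.t.copy(), self.xyz.copy(), self.valid.copy())

    def to_csv(self, path) -> None:
        r = np.sqrt((self.xyz ** 2).sum(axis=1))
        pd.DataFrame(
            {"time_s": self.t, "x_g": self.xyz[:, 0], "y_g": self.xyz[:, 1],
             "z_g": self.xyz[:, 2], "resultant_g": r,
             "valid": self.valid.astype(int)}
        ).to_csv(path, index=False)


def remove_dropouts(
    a: AccelSeries,
    window: int = 5,
    sd_threshold: float = 0.001,
    margin: int = 5,
) -> AccelSeries:
    """Mask flatline dropouts via a 5-point moving standard deviation.

    A sample is a dropout when the centered ``window``-point moving SD
    is below ``sd_threshold`` g on any axis; the ``margin`` samples
    before and after each dropout are masked too.
    """
    if len(a) < window:
        raise ValueError(f"need at least {window} samples")
    out = a.copy()
    flat = np.zeros(len(a), dtype=bool)
    for ax in range(3):
        # full windows only; edge samples inherit the nearest full-window
        # SD rather than an unstable few-sample estimate
        sd = (
            pd.Series(a.xyz[:, ax])
            .rolling(window, center=True, min_periods=window)
            .std()
            .ffill()
            .bfill()
            .to_numpy()
        )
        flat |= sd < sd_threshold
    if flat.any():
        # dilate by `margin` samples on each side
        kernel = np.ones(2 * margin + 1)
        flat = np.convolve(flat.astype(float), kernel, mode="same") > 0
    out.valid &= ~flat
    return out


def trim_outliers(a: AccelSeries, tail: float = 0.05) -> AccelSeries:
    """Mask the extreme ``tail`` percent of valid samples on each axis.

    With ``k = floor(tail/100 * n_valid)``, values strictly below the
    (k+1)-th smallest or strictly above the (k+1)-th largest valid value
    of an axis are masked, so exactly the k most extreme samples go on
    each side when values are distinct and nothing goes for a constant
    axis. Too few valid samples is a warned no-op.
    """
    out = a.copy()
    n_valid = int(out.valid.sum())
    if n_valid == 0 or n_valid < 100.0 / tail:
        warnings.warn("too few valid samples for tail trimming; no-op", stacklevel=2)
        return out
    k = int(np.floor(tail / 100.0 * n_valid))
    if k == 0:
        return out
    drop = np.zeros(len(out), dtype=bool)
    for ax in range(3):
        vals = out.xyz[out.valid, ax]
        srt = np.sort(vals)
        lo, hi = srt[k], srt[-k - 1]
        drop |= out.valid & ((out.xyz[:, ax] < lo) | (out.xyz[:, ax] > hi))
    out.valid &= ~drop
    return out


def resultant(a: AccelSeries):
    """Resultant magnitude over valid samples.

    Returns ``(t, r)`` with ``r = sqrt(x^2 + y^2 + z^2)`` in g, restricted
    to samples marked valid.
    """
    sel = a.valid
    r = np.sqrt((a.xyz[sel] ** 2).sum(axis=1))
    return a.t[sel], r
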