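"""Pressure-signal data model and window/band primitives.

The training device reads two gauge-pressure channels (lip and tongue
cavities of a custom mouthpiece) at a fixed sampling rate.  Everything the
engine computes — calibration offsets, task success scores, game inputs —
reduces to a handful of windowed operations on those uniformly sampled
traces, which live here.

Conventions
-----------
* Pressures are in kPa, times in seconds.
* Time windows are half-open ``[start, end)`` so adjacent cycle windows
  never double-count a sample.
* Band membership is closed ``[lo, hi]``: a pressure sitting exactly on a
  band edge counts as in range.
* Fractions are computed sample-wise (no interpolation of crossing times),
  matching what a sampled digital device actually measures.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Band",
    "Window",
    "PressureTrace",
    "DEFAULT_FS",
    "window_mean",
    "fraction_in_band",
    "fraction_above",
    "apply_offset",
    "read_trace_csv",
    "write_trace_csv",
]

#: Default device sampling rate in Hz.  50 Hz resolves the 1.5 s scored
#: window of a tracking cycle into 75 samples, so a one-sample edge effect
#: changes a cycle fraction by less than 1.5 %.
DEFAULT_FS = 50.0


class Channel(str, enum.Enum):
    """Which mouthpiece cavity a trace was recorded from."""

    LIP = "lip"
    TONGUE = "tongue"


@dataclass(frozen=True)
class Window:
    """A half-open time interval ``[start, end)`` in seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"window end ({self.end}) must exceed start ({self.start})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def shifted(self, dt: float) -> "Window":
        return Window(self.start + dt, self.end + dt)


@dataclass(frozen=True)
class Band:
    """A relative pressure band as fractions of the maximal pressure Pmax."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lo < self.hi <= 1.0):
            raise ValueError(f"band must satisfy 0 <= lo < hi <= 1, got ({self.lo}, {self.hi})")

    def absolute(self, pmax: float) -> tuple[float, float]:
        """The band in kPa for a given maximal pressure."""
        return self.lo * pmax, self.hi * pmax


@dataclass(frozen=True)
class PressureTrace:
    """A uniformly sampled pressure time series for one channel.

    Sample ``i`` is taken at time ``t0 + i / fs``; the trace spans the
    half-open interval ``[t0, t0 + len(values) / fs)``.
    """

    channel: Channel
    values: np.ndarray
    fs: float = DEFAULT_FS
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("trace needs a 1-D array with at least one sample")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace contains non-finite pressures")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel", Channel(self.channel))

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    @property
    def end_time(self) -> float:
        return self.t0 + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs

    def window_indices(self, w: Window) -> tuple[int, int]:
        """Index range ``[i0, i1)`` of samples with times in ``[w.start, w.end)``.

        A tiny negative nudge keeps samples landing exactly on ``w.start``
        inside the window despite floating-point representation of times.
        """
        i0 = math.ceil((w.start - self.t0) * self.fs - 1e-9)
        i1 = math.ceil((w.end - self.t0) * self.fs - 1e-9)
        return max(i0, 0), min(i1, len(self))

    def window_values(self, w: Window) -> np.ndarray:
        i0, i1 = self.window_indices(w)
        if i1 <= i0:
            raise ValueError(
                f"window [{w.start}, {w.end}) outside trace span [{self.t0}, {self.end_time})"
            )
        return self.values[i0:i1]


def window_mean(trace: PressureTrace, w: Window) -> float:
    """Arithmetic mean pressure over the samples falling in ``w``."""
    return float(np.mean(trace.window_values(w)))


def fraction_in_band(trace: PressureTrace, w: Window, lo_kpa: float, hi_kpa: float) -> float:
    """Fraction of samples in ``w`` with pressure in the closed band [lo, hi] kPa."""
    if not lo_kpa < hi_kpa:
        raise ValueError("band lower bound must be below upper bound")
    v = trace.window_values(w)
    return float(np.count_nonzero((v >= lo_kpa) & (v <= hi_kpa)) / v.size)


def fraction_above(trace: PressureTrace, w: Window, threshold_kpa: float) -> float:
    """Fraction of samples in ``w`` with pressure >= threshold."""
    v = trace.window_values(w)
    return float(np.count_nonzero(v >= threshold_kpa) / v.size)


def apply_offset(trace: PressureTrace, offset_kpa: float) -> PressureTrace:
    """Subtract a zero-calibration offset from every sample."""
    return replace(trace, values=trace.values - offset_kpa)


# ---------------------------------------------------------------------------
# Trace CSV I/O: header ``time_s,p_lip_kPa,p_tongue_kPa``, one row per sample.

_CSV_COLUMNS = ["time_s", "p_lip_kPa", "p_tongue_kPa"]


def write_trace_csv(path, lip: PressureTrace, tongue: PressureTrace) -> None:
    """Write a two-channel trace CSV.  Both traces must share fs, t0 and length."""
    if lip.fs != tongue.fs or lip.t0 != tongue.t0 or len(lip) != len(tongue):
        raise ValueError("lip and tongue traces must share time base")
    df = pd.DataFrame(
        {"time_s": lip.times, "p_lip_kPa": lip.values, "p_tongue_kPa": tongue.values}
    )
    df.to_csv(path, index=False)


def read_trace_csv(path) -> dict[Channel, PressureTrace]:
    """Read a two-channel trace CSV, inferring fs from the time column."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV missing columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        fs = DEFAULT_FS
    else:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-4, atol=1e-9):
            raise ValueError("trace CSV is not uniformly sampled")
        fs = 1.0 / float(np.median(dt))
    return {
        Channel.LIP: PressureTrace(Channel.LIP, df["p_lip_kPa"].to_numpy(float), fs=fs, t0=float(t[0])),
        Channel.TONGUE: PressureTrace(
            Channel.TONGUE, df["p_tongue_kPa"].to_numpy(float), fs=fs, t0=float(t[0])
        ),
    }
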