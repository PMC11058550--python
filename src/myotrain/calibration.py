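"""Zero-offset and maximal-pressure calibration.

Two calibrations precede every training block:

* **Zero calibration** — with lips and tongue relaxed, the baseline cavity
  pressure is measured so it can be subtracted from subsequent readings.
  The silicone mouthpiece warms up in the mouth and the trapped-air
  baseline drifts for roughly a minute, so the device calibrates once on
  insertion, plays a two-minute warm-up game while the mouthpiece reaches
  thermal steady state, then calibrates again; the post-warm-up record is
  the authoritative one.  The offset is the mean pressure over the final
  ``zero_window_s`` seconds of the relaxed epoch.

* **Maximal-pressure calibration** — the participant produces maximal
  pressure in ``n_attempts`` (default 3) consecutive attempts.  If the
  maximal absolute deviation of the attempt peaks from their mean, divided
  by the mean, exceeds ``max_rel_dev`` (default 7.5 %), the whole round is
  repeated; otherwise the mean becomes Pmax, the reference all task targets
  are expressed against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .signal_core import Channel, PressureTrace, Window, window_mean

__all__ = [
    "CalibrationPolicy",
    "ZeroCalibration",
    "MaxCalibration",
    "compute_zero_offset",
    "extract_attempt_peaks",
    "evaluate_max_attempts",
    "run_max_calibration",
]


@dataclass(frozen=True)
class CalibrationPolicy:
    """Parameters of both calibration procedures.

    ``deviation`` selects how the attempt spread is summarised: ``"max"``
    (strictest: largest |peak − mean|) or ``"mean"`` (mean absolute
    deviation).
    """

    n_attempts: int = 3
    max_rel_dev: float = 0.075
    max_rounds: int = 5
    zero_window_s: float = 2.0
    deviation: str = "max"

    def __post_init__(self) -> None:
        if self.n_attempts < 2:
            raise ValueError("need at least 2 attempts")
        if not 0.0 < self.max_rel_dev < 1.0:
            raise ValueError("max_rel_dev must be in (0, 1)")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.zero_window_s <= 0:
            raise ValueError("zero_window_s must be positive")
        if self.deviation not in ("max", "mean"):
            raise ValueError("deviation must be 'max' or 'mean'")


@dataclass(frozen=True)
class ZeroCalibration:
    channel: Channel
    offset_kpa: float
    window_duration_s: float
    timestamp_s: float

    def __post_init__(self) -> None:
        if self.window_duration_s <= 0:
            raise ValueError("window duration must be positive")


@dataclass(frozen=True)
class MaxCalibration:
    """Outcome of one maximal-pressure calibration (possibly several rounds).

    ``attempts`` holds the peak pressures of the *last* round evaluated;
    ``mean_kpa`` is their mean and becomes Pmax when ``accepted``.
    """

    channel: Channel
    attempts: tuple[float, ...]
    mean_kpa: float
    rel_dev: float
    accepted: bool
    rounds_used: int = 1

    @property
    def pmax(self) -> float:
        return self.mean_kpa


def compute_zero_offset(
    trace: PressureTrace,
    policy: CalibrationPolicy = CalibrationPolicy(),
    timestamp_s: float | None = None,
) -> ZeroCalibration:
    """Baseline offset = mean pressure over the final ``zero_window_s`` of a relaxed trace."""
    if trace.duration + 1e-9 < policy.zero_window_s:
        raise ValueError(
            f"trace ({trace.duration:.3f} s) shorter than zero window ({policy.zero_window_s} s)"
        )
    w = Window(trace.end_time - policy.zero_window_s, trace.end_time)
    offset = window_mean(trace, w)
    ts = trace.t0 if timestamp_s is None else timestamp_s
    return ZeroCalibration(trace.channel, offset, policy.zero_window_s, ts)


def extract_attempt_peaks(
    trace: PressureTrace, segments: Sequence[Window], n: int | None = None
) -> list[float]:
    """Peak pressure of each marked attempt segment.

    Segment boundaries come from the session layer (the participant presses
    OK after each attempt); ``n`` segments are required (default: all).
    """
    n = len(segments) if n is None else n
    if len(segments) < n:
        raise ValueError(f"need {n} attempt segments, got {len(segments)}")
    return [float(np.max(trace.window_values(w))) for w in segments[:n]]


def evaluate_max_attempts(
    peaks: Sequence[float],
    policy: CalibrationPolicy = CalibrationPolicy(),
    channel: Channel = Channel.TONGUE,
    rounds_used: int = 1,
) -> MaxCalibration:
    """Apply the relative-deviation acceptance rule to one round of peaks.

    The round is accepted iff ``rel_dev <= max_rel_dev`` — the boundary
    counts as accepted, since a repeat is only demanded when the deviation
    is strictly greater than the limit.
    """
    peaks = tuple(float(p) for p in peaks)
    if len(peaks) != policy.n_attempts:
        raise ValueError(f"expected {policy.n_attempts} peaks, got {len(peaks)}")
    if any(p <= 0 for p in peaks):
        raise ValueError("no pressure developed in at least one attempt")
    m = float(np.mean(peaks))
    devs = np.abs(np.asarray(peaks) - m)
    dev = float(np.max(devs) if policy.deviation == "max" else np.mean(devs))
    rel_dev = dev / m
    return MaxCalibration(
        channel=channel,
        attempts=peaks,
        mean_kpa=m,
        rel_dev=rel_dev,
        accepted=rel_dev <= policy.max_rel_dev,
        rounds_used=rounds_used,
    )


def run_max_calibration(
    attempt_source: Iterable[Sequence[float]],
    policy: CalibrationPolicy = CalibrationPolicy(),
    channel: Channel = Channel.TONGUE,
) -> MaxCalibration:
    """Repeat rounds of attempts until one is accepted or ``max_rounds`` is hit.

    ``attempt_source`` yields one tuple of peak pressures per round (all
    ``n_attempts`` attempts are redone on a repeat).  If the source runs dry
    or every round fails, the last round is returned flagged unaccepted
    rather than raising — the session layer decides what to do with it.
    A round containing a non-positive peak is treated as a failed round.
    """
    it = iter(attempt_source)
    last: MaxCalibration | None = None
    for round_idx in range(1, policy.max_rounds + 1):
        try:
            peaks = next(it)
        except StopIteration:
            break
        try:
            last = evaluate_max_attempts(peaks, policy, channel, rounds_used=round_idx)
        except ValueError:
            last = MaxCalibration(
                channel=channel,
                attempts=tuple(float(p) for p in peaks),
                mean_kpa=float(np.mean(peaks)) if len(peaks) else 0.0,
                rel_dev=math.inf,
                accepted=False,
                rounds_used=round_idx,
            )
        if last.accepted:
            return last
    if last is None:
        raise ValueError("attempt source yielded no rounds")
    return last
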