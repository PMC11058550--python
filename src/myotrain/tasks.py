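"""Scoring engines for the pressure-tracking and breathing tasks.

Tracking task (tongue or lip)
    Ten cycles.  Each cycle is 8 s of rest (release the cavity) followed by
    3 s with the target band raised to 3–5 % of Pmax.  The first 1.5 s of
    the target phase let the participant react; the success fraction is the
    percentage of time in band over the *last* 1.5 s only.  The task score
    is 100 × the mean cycle fraction.

Breathing task (lip channel)
    Seven breathing cycles of 8 s inhale + 8 s exhale while continuously
    holding a small lip pressure of at least 4 % of Pmax.  The score is
    100 × the fraction of the whole 112 s spent at or above the threshold;
    the on-screen breathing guide affects display only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .signal_core import Band, Channel, PressureTrace, Window, fraction_above, fraction_in_band, window_mean

__all__ = [
    "TaskKind",
    "TrackingTaskConfig",
    "BreathingTaskConfig",
    "CycleResult",
    "TaskResult",
    "CyclePhases",
    "build_tracking_schedule",
    "score_tracking_task",
    "score_breathing_task",
]


import enum


class TaskKind(str, enum.Enum):
    TONGUE = "tongue"
    LIP = "lip"
    BREATHING = "breathing"


@dataclass(frozen=True)
class TrackingTaskConfig:
    n_cycles: int = 10
    rest_s: float = 8.0
    target_s: float = 3.0
    react_s: float = 1.5
    band: Band = Band(0.03, 0.05)
    channel: Channel = Channel.TONGUE

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if not 0 <= self.react_s < self.target_s:
            raise ValueError("reaction time must be shorter than the target phase")
        if self.rest_s < 0:
            raise ValueError("rest duration cannot be negative")

    @property
    def cycle_s(self) -> float:
        return self.rest_s + self.target_s

    @property
    def total_s(self) -> float:
        return self.n_cycles * self.cycle_s


@dataclass(frozen=True)
class BreathingTaskConfig:
    n_breaths: int = 7
    inhale_s: float = 8.0
    exhale_s: float = 8.0
    threshold_frac: float = 0.04
    channel: Channel = Channel.LIP

    def __post_init__(self) -> None:
        if self.n_breaths < 1:
            raise ValueError("need at least one breath")
        if not 0.0 < self.threshold_frac < 1.0:
            raise ValueError("threshold_frac must be in (0, 1)")

    @property
    def total_s(self) -> float:
        return self.n_breaths * (self.inhale_s + self.exhale_s)


class CyclePhases(NamedTuple):
    """The three windows of one tracking cycle, in task-relative time."""

    rest: Window
    target: Window
    scored: Window


@dataclass(frozen=True)
class CycleResult:
    cycle_index: int
    scored_window: Window
    in_band_fraction: float
    rest_mean_kpa: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.in_band_fraction <= 1.0:
            raise ValueError("cycle fraction must be in [0, 1]")


@dataclass(frozen=True)
class TaskResult:
    task_kind: TaskKind
    score_pct: float
    cycles: tuple[CycleResult, ...] = ()
    pmax_used_kpa: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.score_pct <= 100.0:
            raise ValueError("score must be in [0, 100]")


def build_tracking_schedule(cfg: TrackingTaskConfig) -> list[CyclePhases]:
    """Rest/target/scored windows for every cycle, starting at t = 0.

    Cycle ``k`` rests over ``[k·C, k·C + rest)``, tracks the raised band over
    the next ``target_s``, and is scored over the final ``target_s − react_s``
    of the target phase (``[9.5, 11.0)`` s for cycle 0 at defaults).
    """
    out = []
    for k in range(cfg.n_cycles):
        start = k * cfg.cycle_s
        rest = Window(start, start + cfg.rest_s)
        target = Window(rest.end, rest.end + cfg.target_s)
        scored = Window(target.start + cfg.react_s, target.end)
        out.append(CyclePhases(rest, target, scored))
    return out


def _check_coverage(trace: PressureTrace, needed_s: float) -> None:
    # allow half a sample of slack at the end
    if trace.duration + 0.5 / trace.fs < needed_s:
        raise ValueError(
            f"trace ({trace.duration:.2f} s) shorter than task schedule ({needed_s:.2f} s)"
        )


def score_tracking_task(trace: PressureTrace, cfg: TrackingTaskConfig, pmax_kpa: float) -> TaskResult:
    """Score a tracking task from a (zero-corrected) trace and the session Pmax.

    Per cycle the in-band fraction is computed over the scored window with
    the band made absolute, ``[band.lo·Pmax, band.hi·Pmax]`` kPa.  Pressure
    behaviour during rest and reaction windows never affects the score; the
    mean rest pressure is logged per cycle for quality control only.
    """
    if not pmax_kpa > 0:
        raise ValueError("Pmax must be positive")
    _check_coverage(trace, cfg.total_s)
    lo, hi = cfg.band.absolute(pmax_kpa)
    cycles = []
    for k, phases in enumerate(build_tracking_schedule(cfg)):
        scored = phases.scored.shifted(trace.t0)
        frac = fraction_in_band(trace, scored, lo, hi)
        rest_mean = window_mean(trace, phases.rest.shifted(trace.t0)) if cfg.rest_s > 0 else float("nan")
        cycles.append(CycleResult(k, phases.scored, frac, rest_mean))
    score = 100.0 * float(np.mean([c.in_band_fraction for c in cycles]))
    kind = TaskKind.TONGUE if cfg.channel == Channel.TONGUE else TaskKind.LIP
    return TaskResult(kind, score, tuple(cycles), pmax_kpa)


def score_breathing_task(trace: PressureTrace, cfg: BreathingTaskConfig, pmax_kpa: float) -> TaskResult:
    """Score a breathing task: fraction of the whole task spent above threshold."""
    if not pmax_kpa > 0:
        raise ValueError("Pmax must be positive")
    _check_coverage(trace, cfg.total_s)
    w = Window(trace.t0, trace.t0 + cfg.total_s)
    frac = fraction_above(trace, w, cfg.threshold_frac * pmax_kpa)
    return TaskResult(TaskKind.BREATHING, 100.0 * frac, (), pmax_kpa)
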