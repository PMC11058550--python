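"""The training-session state machine and session-log I/O.

A full session follows the device's flow chart:

    zero calibration → 2-minute warm-up game (thermal equilibration)
    → zero calibration (authoritative) → maximal-pressure calibration,
    tongue then lips → 4 rounds of [zero calibration, breathing task,
    lip task, tongue task, game]

so a completed default session contains 4 breathing, 4 lip and 4 tongue
tasks plus 4 post-warm-up games, lasts roughly 35 minutes, and every task
is scored against the Pmax established by that session's max calibration.
Results are archived to a structured JSON log that round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Optional, Protocol

import numpy as np

from .calibration import (
    CalibrationPolicy,
    MaxCalibration,
    ZeroCalibration,
    compute_zero_offset,
    extract_attempt_peaks,
    run_max_calibration,
)
from .games import GameResult, GameRules, GameVariant, run_game
from .signal_core import Channel, PressureTrace, Window, apply_offset
from .tasks import (
    BreathingTaskConfig,
    CycleResult,
    TaskKind,
    TaskResult,
    TrackingTaskConfig,
    score_breathing_task,
    score_tracking_task,
)

__all__ = [
    "StepKind",
    "PlanStep",
    "SessionConfig",
    "SessionPlan",
    "SessionRecord",
    "ParticipantLog",
    "UserLike",
    "build_session_plan",
    "run_session",
    "write_session_log",
    "read_session_log",
    "SessionLogError",
]

SCHEMA_VERSION = 1

#: Fallback Pmax (kPa) used to score tasks when the max calibration never
#: reaches acceptance and its last round carries no positive mean.
FALLBACK_PMAX_KPA = 10.0


class StepKind(str, enum.Enum):
    ZERO_CAL = "zero_cal"
    WARM_UP_GAME = "warm_up_game"
    MAX_CAL = "max_cal"
    BREATHING = "breathing"
    LIP_TASK = "lip_task"
    TONGUE_TASK = "tongue_task"
    GAME = "game"


@dataclass(frozen=True)
class PlanStep:
    kind: StepKind
    channel: Optional[Channel] = None
    duration_s: float = 0.0
    game_variant: Optional[GameVariant] = None
    round_index: Optional[int] = None


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to lay out and run one session."""

    rounds: int = 4
    fs: float = 50.0
    warm_up_s: float = 120.0
    warm_up_variant: GameVariant = GameVariant.PADDLE
    game_duration_s: float = 120.0
    zero_cal_s: float = 10.0
    max_cal_round_s: float = 20.0
    calibration: CalibrationPolicy = CalibrationPolicy()
    tongue_task: TrackingTaskConfig = TrackingTaskConfig(channel=Channel.TONGUE)
    lip_task: TrackingTaskConfig = TrackingTaskConfig(channel=Channel.LIP)
    breathing_task: BreathingTaskConfig = BreathingTaskConfig()
    zero_per_task: bool = False  # re-zero before every task instead of every round

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("need at least one round")
        if self.zero_cal_s < self.calibration.zero_window_s:
            raise ValueError("zero-cal step shorter than its measurement window")


@dataclass(frozen=True)
class SessionPlan:
    steps: tuple[PlanStep, ...]
    config: SessionConfig

    def count(self, kind: StepKind) -> int:
        return sum(1 for s in self.steps if s.kind == kind)

    @property
    def scheduled_duration_s(self) -> float:
        """Nominal duration assuming single-round calibrations."""
        return sum(s.duration_s for s in self.steps)


def build_session_plan(config: SessionConfig = SessionConfig(), seed: int = 0) -> SessionPlan:
    """Lay out the ordered step list of one session.

    Game variants rotate round-robin through the four games in a seeded
    order, so across rounds every game appears once at default settings.
    A zero calibration precedes every round of tasks (or every task when
    ``zero_per_task`` is set).
    """
    cfg = config
    rng = np.random.default_rng(seed)
    order = [GameVariant.PADDLE, GameVariant.CIRCLE, GameVariant.MISSILE, GameVariant.WALL]
    order = [order[i] for i in rng.permutation(len(order))]

    steps: list[PlanStep] = [
        PlanStep(StepKind.ZERO_CAL, duration_s=cfg.zero_cal_s),
        PlanStep(StepKind.WARM_UP_GAME, duration_s=cfg.warm_up_s, game_variant=cfg.warm_up_variant),
        PlanStep(StepKind.ZERO_CAL, duration_s=cfg.zero_cal_s),
        PlanStep(StepKind.MAX_CAL, channel=Channel.TONGUE, duration_s=cfg.max_cal_round_s),
        PlanStep(StepKind.MAX_CAL, channel=Channel.LIP, duration_s=cfg.max_cal_round_s),
    ]
    task_steps = (
        (StepKind.BREATHING, None, cfg.breathing_task.total_s),
        (StepKind.LIP_TASK, Channel.LIP, cfg.lip_task.total_s),
        (StepKind.TONGUE_TASK, Channel.TONGUE, cfg.tongue_task.total_s),
    )
    for r in range(cfg.rounds):
        if not cfg.zero_per_task:
            steps.append(PlanStep(StepKind.ZERO_CAL, duration_s=cfg.zero_cal_s, round_index=r))
        for kind, channel, dur in task_steps:
            if cfg.zero_per_task:
                steps.append(PlanStep(StepKind.ZERO_CAL, duration_s=cfg.zero_cal_s, round_index=r))
            steps.append(PlanStep(kind, channel=channel, duration_s=dur, round_index=r))
        steps.append(
            PlanStep(
                StepKind.GAME,
                duration_s=cfg.game_duration_s,
                game_variant=order[r % len(order)],
                round_index=r,
            )
        )
    return SessionPlan(tuple(steps), cfg)


@dataclass
class SessionRecord:
    """Everything archived for one training day."""

    participant_id: str
    day_index: int
    completed: bool
    zero_cals: list[ZeroCalibration] = field(default_factory=list)
    max_cals: dict[Channel, MaxCalibration] = field(default_factory=dict)
    task_results: list[TaskResult] = field(default_factory=list)
    game_results: list[GameResult] = field(default_factory=list)
    total_duration_s: float = 0.0
    timestamp: str = ""  # ISO-8601 date of the session
    reason: str = ""

    def pmax(self, channel: Channel) -> float:
        return self.max_cals[channel].pmax


@dataclass
class ParticipantLog:
    """A participant's 4-week record: the unit all analytics operate on."""

    participant_id: str
    prescribed_days: list[int]
    sessions: list[SessionRecord] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)
    start_date: str = "2024-01-01"

    @property
    def n_prescribed(self) -> int:
        return len(self.prescribed_days)

    @property
    def n_completed(self) -> int:
        return sum(1 for s in self.sessions if s.completed)


class UserLike(Protocol):
    """What the session engine needs from a (simulated or replayed) user."""

    def zero_trace(
        self, channel: Channel, duration_s: float, t_start: float, fs: float, rng: np.random.Generator
    ) -> PressureTrace: ...

    def max_attempt_trace(
        self, channel: Channel, n: int, t_start: float, fs: float, rng: np.random.Generator
    ) -> tuple[PressureTrace, list[Window]]: ...

    def tracking_trace(
        self, cfg: TrackingTaskConfig, pmax: float, t_start: float, fs: float, rng: np.random.Generator
    ) -> PressureTrace: ...

    def breathing_trace(
        self, cfg: BreathingTaskConfig, pmax: float, t_start: float, fs: float, rng: np.random.Generator
    ) -> PressureTrace: ...

    def game_controller(self, variant: GameVariant, rng: np.random.Generator): ...


def run_session(
    user: UserLike,
    plan: SessionPlan | None = None,
    seed: int = 0,
    participant_id: str = "sim",
    day_index: int = 1,
    timestamp: str = "",
) -> SessionRecord:
    """Execute a session plan against a user model.

    The engine keeps a running session clock, maintains the latest zero
    offset per channel (applied to every subsequent trace), and carries the
    accepted Pmax from the max-calibration steps into all task scoring.  If
    a max calibration is never accepted the session continues on a fallback
    Pmax but the record is flagged ``completed=False`` with a reason.
    Deterministic given (user, plan, seed).
    """
    plan = plan if plan is not None else build_session_plan()
    cfg = plan.config
    rng = np.random.default_rng(seed)
    record = SessionRecord(participant_id, day_index, completed=False, timestamp=timestamp)
    t = 0.0
    offsets: dict[Channel, float] = {Channel.LIP: 0.0, Channel.TONGUE: 0.0}
    pmax: dict[Channel, float] = {}
    cal_failed = False

    def corrected(trace: PressureTrace) -> PressureTrace:
        return apply_offset(trace, offsets[trace.channel])

    for step in plan.steps:
        if step.kind == StepKind.ZERO_CAL:
            for ch in (Channel.TONGUE, Channel.LIP):
                trace = user.zero_trace(ch, step.duration_s, t, cfg.fs, rng)
                zc = compute_zero_offset(trace, cfg.calibration, timestamp_s=t)
                offsets[ch] = zc.offset_kpa
                record.zero_cals.append(zc)
            t += step.duration_s

        elif step.kind in (StepKind.WARM_UP_GAME, StepKind.GAME):
            rules = GameRules(variant=step.game_variant, fs=cfg.fs)
            controller = user.game_controller(step.game_variant, rng)
            game_seed = int(rng.integers(0, 2**31 - 1))
            result = run_game(rules, controller, step.duration_s, seed=game_seed)
            record.game_results.append(result)
            t += step.duration_s

        elif step.kind == StepKind.MAX_CAL:
            ch = step.channel

            def attempt_rounds():
                while True:
                    trace, segments = user.max_attempt_trace(
                        ch, cfg.calibration.n_attempts, t, cfg.fs, rng
                    )
                    yield extract_attempt_peaks(corrected(trace), segments)

            cal = run_max_calibration(attempt_rounds(), cfg.calibration, ch)
            record.max_cals[ch] = cal
            if cal.accepted:
                pmax[ch] = cal.pmax
            else:
                cal_failed = True
                pmax[ch] = cal.mean_kpa if cal.mean_kpa > 0 else FALLBACK_PMAX_KPA
            t += step.duration_s * cal.rounds_used

        elif step.kind == StepKind.BREATHING:
            bcfg = cfg.breathing_task
            trace = user.breathing_trace(bcfg, pmax[bcfg.channel], t, cfg.fs, rng)
            record.task_results.append(score_breathing_task(corrected(trace), bcfg, pmax[bcfg.channel]))
            t += step.duration_s

        else:  # LIP_TASK or TONGUE_TASK
            tcfg = cfg.lip_task if step.kind == StepKind.LIP_TASK else cfg.tongue_task
            trace = user.tracking_trace(tcfg, pmax[tcfg.channel], t, cfg.fs, rng)
            record.task_results.append(score_tracking_task(corrected(trace), tcfg, pmax[tcfg.channel]))
            t += step.duration_s

    record.total_duration_s = t
    n_tasks_planned = sum(
        plan.count(k) for k in (StepKind.BREATHING, StepKind.LIP_TASK, StepKind.TONGUE_TASK)
    )
    record.completed = len(record.task_results) == n_tasks_planned and not cal_failed
    if cal_failed:
        record.reason = "max calibration not accepted; tasks scored against fallback Pmax"
    return record


# ---------------------------------------------------------------------------
# Log serialization: one JSON document per participant (or single record),
# schema-versioned, exact round-trip.


class SessionLogError(ValueError):
    """Raised when a session log cannot be parsed; names the offending field."""


def _encode(obj):
    if isinstance(obj, (ZeroCalibration, MaxCalibration, TaskResult, CycleResult, GameResult, Window)):
        return {k: _encode(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, dict):
        return {(k.value if isinstance(k, enum.Enum) else k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _record_to_dict(r: SessionRecord) -> dict:
    return {
        "participant_id": r.participant_id,
        "day_index": r.day_index,
        "completed": r.completed,
        "zero_cals": [_encode(z) for z in r.zero_cals],
        "max_cals": {ch.value: _encode(mc) for ch, mc in r.max_cals.items()},
        "task_results": [_encode(tr) for tr in r.task_results],
        "game_results": [_encode(g) for g in r.game_results],
        "total_duration_s": r.total_duration_s,
        "timestamp": r.timestamp,
        "reason": r.reason,
    }


def _require(d: dict, key: str, context: str):
    try:
        return d[key]
    except (KeyError, TypeError) as exc:
        raise SessionLogError(f"missing field '{key}' in {context}") from exc


def _record_from_dict(d: dict) -> SessionRecord:
    ctx = "session record"
    cycles = lambda cs: tuple(
        CycleResult(
            c["cycle_index"],
            Window(c["scored_window"]["start"], c["scored_window"]["end"]),
            c["in_band_fraction"],
            c.get("rest_mean_kpa", float("nan")),
        )
        for c in cs
    )
    return SessionRecord(
        participant_id=_require(d, "participant_id", ctx),
        day_index=_require(d, "day_index", ctx),
        completed=_require(d, "completed", ctx),
        zero_cals=[
            ZeroCalibration(Channel(z["channel"]), z["offset_kpa"], z["window_duration_s"], z["timestamp_s"])
            for z in _require(d, "zero_cals", ctx)
        ],
        max_cals={
            Channel(ch): MaxCalibration(
                Channel(mc["channel"]),
                tuple(mc["attempts"]),
                mc["mean_kpa"],
                mc["rel_dev"],
                mc["accepted"],
                mc["rounds_used"],
            )
            for ch, mc in _require(d, "max_cals", ctx).items()
        },
        task_results=[
            TaskResult(TaskKind(tr["task_kind"]), tr["score_pct"], cycles(tr["cycles"]), tr["pmax_used_kpa"])
            for tr in _require(d, "task_results", ctx)
        ],
        game_results=[
            GameResult(GameVariant(g["variant"]), g["final_score"], g["high_score"], g["duration_s"], g["n_steps"])
            for g in _require(d, "game_results", ctx)
        ],
        total_duration_s=_require(d, "total_duration_s", ctx),
        timestamp=d.get("timestamp", ""),
        reason=d.get("reason", ""),
    )


def write_session_log(log: ParticipantLog | SessionRecord, path) -> None:
    """Archive a participant log (or a single session record) as JSON."""
    if isinstance(log, SessionRecord):
        doc = {"schema_version": SCHEMA_VERSION, "type": "session", "session": _record_to_dict(log)}
    else:
        doc = {
            "schema_version": SCHEMA_VERSION,
            "type": "participant",
            "participant_id": log.participant_id,
            "start_date": log.start_date,
            "prescribed_days": list(log.prescribed_days),
            "covariates": dict(log.covariates),
            "sessions": [_record_to_dict(s) for s in log.sessions],
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)


def read_session_log(path) -> ParticipantLog | SessionRecord:
    """Parse a session log written by :func:`write_session_log`."""
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionLogError(f"malformed session log {path}: {exc}") from exc
    kind = _require(doc, "type", "log document")
    if kind == "session":
        return _record_from_dict(_require(doc, "session", "log document"))
    if kind != "participant":
        raise SessionLogError(f"unknown log type '{kind}'")
    return ParticipantLog(
        participant_id=_require(doc, "participant_id", "participant log"),
        prescribed_days=list(_require(doc, "prescribed_days", "participant log")),
        sessions=[_record_from_dict(s) for s in _require(doc, "sessions", "participant log")],
        covariates=dict(doc.get("covariates", {})),
        start_date=doc.get("start_date", ""),
    )


def session_date(start_date: str, day_index: int) -> str:
    """ISO date of a given 1-based study day."""
    return (date.fromisoformat(start_date) + timedelta(days=day_index - 1)).isoformat()
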