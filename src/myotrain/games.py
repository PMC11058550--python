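"""The four pressure-driven training games as deterministic state machines.

The games sit between the metered tasks purely to keep participants
engaged; their scores are logged but excluded from success-rate analytics.
Each game runs on a fixed timestep (``1 / fs``) over a 1×1 unitless field
and is fully deterministic given (rules, seed, input stream), which makes
bit-identical replay possible.

Variants
--------
paddle
    A ball bounces between top/bottom walls and two side paddles whose
    vertical position is proportional to lip (left, blue) and tongue
    (right, green) pressure.  Each paddle bounce increments the counter and
    speeds the ball up; a miss resets the counter.
circle
    Lip pressure moves a point horizontally, tongue pressure vertically.
    Hold the point inside the displayed circle for 3 s to score; the circle
    then shrinks and relocates and 7 s are added to a countdown that starts
    at 30 s; when the countdown expires the score resets.
missile
    A small tongue press-then-release fires a coloured missile at a wheel
    of 6 coloured sectors; lip pressure rotates the wheel.  Matching colour
    on impact scores and speeds up the next missile.
wall
    A ball flies toward a wall with a hole.  A lip press-release moves the
    hole up one increment, a tongue press-release moves it down.  A ball
    through the hole scores and the next ball is faster at a new seeded
    height.

All numeric constants (speeds, sizes, increments, press-release
hysteresis) are configurable defaults of this implementation, not claims
about the clinical device.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "GameVariant",
    "GameRules",
    "GameInput",
    "GameResult",
    "PaddleState",
    "CircleState",
    "MissileState",
    "WallState",
    "make_initial_state",
    "step_game",
    "run_game",
]


class GameVariant(str, enum.Enum):
    PADDLE = "paddle"
    CIRCLE = "circle"
    MISSILE = "missile"
    WALL = "wall"


@dataclass(frozen=True)
class GameRules:
    """Physics and scoring constants shared by all variants.

    Pressures arrive already normalised by Pmax; ``pressure_ref_frac`` is
    the fraction of Pmax that maps to full field deflection (10 % by
    default so games stay effortless relative to the tasks).
    """

    variant: GameVariant
    fs: float = 50.0
    initial_speed: float = 0.5          # field units / s
    speed_growth: float = 1.1           # per success
    pressure_ref_frac: float = 0.10
    paddle_len: float = 0.2
    circle_r0: float = 0.15
    circle_shrink: float = 0.9
    circle_rmin: float = 0.05
    circle_dwell_s: float = 3.0
    circle_timer0_s: float = 30.0
    circle_bonus_s: float = 7.0
    press_on_frac: float = 0.02         # press-release detector hysteresis
    press_off_frac: float = 0.01
    n_sectors: int = 6
    wall_step: float = 0.1
    wall_hole_halfwidth: float = 0.05

    def __post_init__(self) -> None:
        if self.initial_speed <= 0 or self.fs <= 0:
            raise ValueError("speeds and sampling rate must be positive")
        if self.speed_growth < 1.0:
            raise ValueError("speed growth factor must be >= 1")
        object.__setattr__(self, "variant", GameVariant(self.variant))

    @property
    def dt(self) -> float:
        return 1.0 / self.fs


@dataclass(frozen=True)
class GameInput:
    """Lip and tongue pressures as non-negative fractions of Pmax."""

    p_lip: float = 0.0
    p_tongue: float = 0.0

    def __post_init__(self) -> None:
        if self.p_lip < 0 or self.p_tongue < 0:
            raise ValueError("pressures must be non-negative")


def _deflect(pressure_frac: float, rules: GameRules) -> float:
    """Map a pressure fraction to a [0, 1] field coordinate."""
    return min(max(pressure_frac / rules.pressure_ref_frac, 0.0), 1.0)


class _PressRelease:
    """Hysteresis detector: fires on release after a press above ``on``."""

    __slots__ = ("armed",)

    def __init__(self) -> None:
        self.armed = False

    def update(self, p: float, on: float, off: float) -> bool:
        if not self.armed:
            if p >= on:
                self.armed = True
            return False
        if p <= off:
            self.armed = False
            return True
        return False


@dataclass
class _BaseState:
    score: int = 0
    high_score: int = 0

    def _bump(self) -> None:
        self.score += 1
        self.high_score = max(self.high_score, self.score)


@dataclass
class PaddleState(_BaseState):
    ball_x: float = 0.5
    ball_y: float = 0.5
    vx: float = 0.0
    vy: float = 0.0
    speed: float = 0.0
    lip_paddle_y: float = 0.0
    tongue_paddle_y: float = 0.0


@dataclass
class CircleState(_BaseState):
    point_x: float = 0.0
    point_y: float = 0.0
    center_x: float = 0.5
    center_y: float = 0.5
    radius: float = 0.15
    dwell_s: float = 0.0
    countdown_s: float = 30.0


@dataclass
class MissileState(_BaseState):
    missile_y: float = -1.0             # < 0: no missile in flight
    missile_color: int = 0
    wheel_sector: int = 0
    speed: float = 0.0
    _detector: _PressRelease = field(default_factory=_PressRelease)


@dataclass
class WallState(_BaseState):
    ball_x: float = 0.0
    ball_y: float = 0.5
    hole_y: float = 0.5
    speed: float = 0.0
    _lip_detector: _PressRelease = field(default_factory=_PressRelease)
    _tongue_detector: _PressRelease = field(default_factory=_PressRelease)


_STATE_CLASSES = {
    GameVariant.PADDLE: PaddleState,
    GameVariant.CIRCLE: CircleState,
    GameVariant.MISSILE: MissileState,
    GameVariant.WALL: WallState,
}


def make_initial_state(rules: GameRules, rng: np.random.Generator):
    """Fresh state for ``rules.variant`` with seeded initial geometry."""
    v = rules.variant
    if v == GameVariant.PADDLE:
        s = PaddleState(speed=rules.initial_speed)
        _serve_ball(s, rules, rng)
        return s
    if v == GameVariant.CIRCLE:
        s = CircleState(radius=rules.circle_r0, countdown_s=rules.circle_timer0_s)
        _relocate_circle(s, rules, rng)
        return s
    if v == GameVariant.MISSILE:
        return MissileState(speed=rules.initial_speed)
    s = WallState(speed=rules.initial_speed)
    _new_wall_ball(s, rules, rng)
    return s


def _serve_ball(s: PaddleState, rules: GameRules, rng: np.random.Generator) -> None:
    s.ball_x, s.ball_y = 0.5, 0.5
    angle = rng.uniform(-math.pi / 4, math.pi / 4)
    direction = 1.0 if rng.random() < 0.5 else -1.0
    s.vx = direction * s.speed * math.cos(angle)
    s.vy = s.speed * math.sin(angle)


def _relocate_circle(s: CircleState, rules: GameRules, rng: np.random.Generator) -> None:
    r = s.radius
    s.center_x = float(rng.uniform(r, 1.0 - r))
    s.center_y = float(rng.uniform(r, 1.0 - r))


def _new_wall_ball(s: WallState, rules: GameRules, rng: np.random.Generator) -> None:
    hw = rules.wall_hole_halfwidth
    s.ball_x = 0.0
    s.ball_y = float(rng.uniform(hw, 1.0 - hw))


def _rescale_velocity(s: PaddleState) -> None:
    norm = math.hypot(s.vx, s.vy)
    if norm > 0:
        s.vx *= s.speed / norm
        s.vy *= s.speed / norm


def _step_paddle(s: PaddleState, inp: GameInput, rules: GameRules, rng) -> None:
    span = 1.0 - rules.paddle_len
    s.lip_paddle_y = min(_deflect(inp.p_lip, rules), 1.0) * span
    s.tongue_paddle_y = min(_deflect(inp.p_tongue, rules), 1.0) * span
    s.ball_x += s.vx * rules.dt
    s.ball_y += s.vy * rules.dt
    if s.ball_y < 0.0:
        s.ball_y = -s.ball_y
        s.vy = abs(s.vy)
    elif s.ball_y > 1.0:
        s.ball_y = 2.0 - s.ball_y
        s.vy = -abs(s.vy)
    for x_edge, paddle_y, sign in ((0.0, s.lip_paddle_y, 1.0), (1.0, s.tongue_paddle_y, -1.0)):
        crossed = s.ball_x <= x_edge if x_edge == 0.0 else s.ball_x >= x_edge
        if crossed:
            if paddle_y <= s.ball_y <= paddle_y + rules.paddle_len:
                s.ball_x = x_edge + sign * (x_edge - s.ball_x if x_edge == 0.0 else s.ball_x - x_edge)
                s.ball_x = min(max(s.ball_x, 0.0), 1.0)
                s.vx = sign * abs(s.vx)
                s.speed *= rules.speed_growth
                _rescale_velocity(s)
                s._bump()
            else:
                s.score = 0
                s.speed = rules.initial_speed
                _serve_ball(s, rules, rng)
            break


def _step_circle(s: CircleState, inp: GameInput, rules: GameRules, rng) -> None:
    s.point_x = _deflect(inp.p_lip, rules)
    s.point_y = _deflect(inp.p_tongue, rules)
    inside = math.hypot(s.point_x - s.center_x, s.point_y - s.center_y) <= s.radius
    s.dwell_s = s.dwell_s + rules.dt if inside else 0.0
    s.countdown_s -= rules.dt
    if s.dwell_s >= rules.circle_dwell_s - 1e-9:
        s._bump()
        s.radius = max(rules.circle_rmin, s.radius * rules.circle_shrink)
        _relocate_circle(s, rules, rng)
        s.countdown_s += rules.circle_bonus_s
        s.dwell_s = 0.0
    elif s.countdown_s <= 1e-9:
        s.score = 0
        s.countdown_s = rules.circle_timer0_s


def _step_missile(s: MissileState, inp: GameInput, rules: GameRules, rng) -> None:
    s.wheel_sector = min(int(_deflect(inp.p_lip, rules) * rules.n_sectors), rules.n_sectors - 1)
    fired = s._detector.update(inp.p_tongue, rules.press_on_frac, rules.press_off_frac)
    if fired and s.missile_y < 0.0:
        s.missile_y = 0.0
        s.missile_color = int(rng.integers(rules.n_sectors))
    if s.missile_y >= 0.0:
        s.missile_y += s.speed * rules.dt
        if s.missile_y >= 1.0:
            if s.wheel_sector == s.missile_color:
                s._bump()
                s.speed *= rules.speed_growth
            else:
                s.score = 0
            s.missile_y = -1.0


def _step_wall(s: WallState, inp: GameInput, rules: GameRules, rng) -> None:
    hw = rules.wall_hole_halfwidth
    if s._lip_detector.update(inp.p_lip, rules.press_on_frac, rules.press_off_frac):
        s.hole_y = min(s.hole_y + rules.wall_step, 1.0 - hw)
    if s._tongue_detector.update(inp.p_tongue, rules.press_on_frac, rules.press_off_frac):
        s.hole_y = max(s.hole_y - rules.wall_step, hw)
    s.ball_x += s.speed * rules.dt
    if s.ball_x >= 1.0:
        if abs(s.ball_y - s.hole_y) <= hw:
            s._bump()
            s.speed *= rules.speed_growth
        else:
            s.score = 0
            s.speed = rules.initial_speed
        _new_wall_ball(s, rules, rng)


_STEPPERS = {
    GameVariant.PADDLE: _step_paddle,
    GameVariant.CIRCLE: _step_circle,
    GameVariant.MISSILE: _step_missile,
    GameVariant.WALL: _step_wall,
}


def step_game(state, inp: GameInput, rules: GameRules, rng: np.random.Generator):
    """Advance one fixed timestep; mutates and returns ``state``.

    ``rng`` drives seeded relocations/colours; passing the same generator
    state reproduces the exact trajectory.
    """
    if not isinstance(state, _STATE_CLASSES[rules.variant]):
        raise TypeError(f"state {type(state).__name__} does not match variant {rules.variant.value}")
    _STEPPERS[rules.variant](state, inp, rules, rng)
    return state


@dataclass(frozen=True)
class GameResult:
    variant: GameVariant
    final_score: int
    high_score: int
    duration_s: float
    n_steps: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "variant", GameVariant(self.variant))


Controller = Callable[[float, object], GameInput]


def run_game(
    rules: GameRules,
    controller: Controller,
    duration_s: float,
    seed: int,
    record: bool = False,
) -> GameResult | tuple[GameResult, list]:
    """Run a game for ``duration_s`` seconds with a pressure controller.

    ``controller(t, state) -> GameInput`` supplies the pressures at each
    step.  The run is deterministic given (rules, controller, seed).  With
    ``record=True`` a per-step log of (t, score, key positions) is returned
    alongside the result, for replay tests.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    state = make_initial_state(rules, rng)
    n_steps = round(duration_s * rules.fs)
    log: list = []
    for i in range(n_steps):
        t = i * rules.dt
        step_game(state, controller(t, state), rules, rng)
        if record:
            log.append(_snapshot(t, state))
    result = GameResult(rules.variant, state.score, state.high_score, duration_s, n_steps)
    return (result, log) if record else result


def _snapshot(t: float, state) -> tuple:
    if isinstance(state, PaddleState):
        return (t, state.score, state.ball_x, state.ball_y, state.vx, state.vy)
    if isinstance(state, CircleState):
        return (t, state.score, state.point_x, state.point_y, state.center_x, state.center_y, state.dwell_s)
    if isinstance(state, MissileState):
        return (t, state.score, state.missile_y, state.wheel_sector, state.missile_color)
    return (t, state.score, state.ball_x, state.ball_y, state.hole_y)
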