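"""Synthetic users and cohorts for the training device.

No raw recordings exist for this kind of study, so every downstream module
is exercised against simulated participants.  The simulator emulates the
statistical structure the clinical evaluation relies on:

* **Pressure production** — during a tracking target the participant
  approaches the band centre with a reaction latency and first-order
  dynamics, then holds it with white Gaussian noise.  The noise amplitude
  is inverted from the programmed skill level (see
  :func:`sigma_for_skill`), so the per-sample in-band probability in the
  scored part of a cycle equals ``skill(day)`` exactly.
* **Learning** — skill follows an exponential approach from ``skill_0``
  toward ``skill_inf`` with time constant ``kappa_days``, emulating the
  observed rise in success rates over the 4-week programme.
* **Thermal drift** — the mouthpiece baseline rises as
  ``b_inf · (1 − e^(−t/tau))`` after insertion, reaching steady state in
  about a minute: the reason the device re-zeroes after the warm-up game.
* **Adherence** — each prescribed day is attended with a Bernoulli
  adherence probability; dropout is a geometric daily hazard (the default
  yields roughly 20 % dropout over 4 weeks).
* **Clinical covariates** — pre/post apnea-hypopnea indices (AHI) are
  generated with a rank-based Gaussian copula tying the change in supine
  AHI to the participant's lip-score improvement at a programmable
  Spearman correlation (negative by default: more lip improvement, larger
  supine-AHI drop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .games import GameInput, GameVariant
from .session import (
    ParticipantLog,
    SessionConfig,
    build_session_plan,
    run_session,
    session_date,
)
from .signal_core import Channel, PressureTrace, Window
from .tasks import BreathingTaskConfig, TrackingTaskConfig, build_tracking_schedule

__all__ = [
    "ThermalModel",
    "UserModel",
    "CohortConfig",
    "thermal_offset",
    "sigma_for_skill",
    "SimulatedUser",
    "generate_user_trace",
    "simulate_attendance",
    "generate_covariates",
    "simulate_participant",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ThermalModel:
    """First-order thermal baseline drift of the mouthpiece cavities."""

    b_inf_kpa: float = 0.3
    tau_s: float = 20.0

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("thermal time constant must be positive")


def thermal_offset(t_s: float | np.ndarray, model: ThermalModel) -> float | np.ndarray:
    """Baseline offset ``b_inf · (1 − e^(−t/tau))`` at time ``t`` after insertion."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = model.b_inf_kpa * (1.0 - np.exp(-t / model.tau_s))
    return float(out) if np.isscalar(t_s) else out


def sigma_for_skill(skill: float, half_width_kpa: float) -> float:
    """Noise SD giving a target in-band probability around the band centre.

    For pressure ``N(c, σ²)`` and a band of half-width ``h`` about ``c``,
    ``P(in band) = 2·Φ(h/σ) − 1``.  Inverting: ``σ = h / Φ⁻¹((1+skill)/2)``.
    ``skill → 1`` gives σ → 0 (returned as exactly 0 above 1 − 1e−9).
    """
    if not 0.0 <= skill <= 1.0:
        raise ValueError("skill must be in [0, 1]")
    if skill >= 1.0 - 1e-9:
        return 0.0
    if skill <= 0.0:
        return math.inf
    return half_width_kpa / stats.norm.ppf((1.0 + skill) / 2.0)


@dataclass(frozen=True)
class UserModel:
    """Parameters of one synthetic participant.

    Default maximal pressures are typical of healthy adults on comparable
    tongue/lip manometry (tongue ≈ 40 kPa, lips ≈ 20 kPa).  Default skill
    endpoints follow the observed group trajectory (≈66 % first-day
    success rising toward the high 80s).
    """

    pmax_tongue_kpa: float = 40.0
    pmax_lip_kpa: float = 20.0
    skill_0: float = 0.66
    skill_inf: float = 0.87
    kappa_days: float = 10.0
    latency_s: float = 0.5
    approach_tau_s: float = 0.3
    rest_noise_frac: float = 0.002
    breathing_noise_frac: float = 0.01
    attempt_var: float = 0.03
    adherence: float = 0.92
    dropout_hazard: float = 0.008
    thermal: ThermalModel = ThermalModel()

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill_0 <= self.skill_inf <= 1.0:
            raise ValueError("need 0 <= skill_0 <= skill_inf <= 1")
        if self.latency_s < 0 or self.kappa_days <= 0:
            raise ValueError("latency must be >= 0 and kappa_days > 0")
        if not 0.0 <= self.adherence <= 1.0 or not 0.0 <= self.dropout_hazard <= 1.0:
            raise ValueError("adherence and dropout hazard are probabilities")

    def pmax(self, channel: Channel) -> float:
        return self.pmax_tongue_kpa if channel == Channel.TONGUE else self.pmax_lip_kpa

    def skill(self, day: int | float) -> float:
        """In-band probability on study day ``day`` (exponential learning)."""
        return self.skill_inf - (self.skill_inf - self.skill_0) * math.exp(-day / self.kappa_days)


class SimulatedUser:
    """Binds a :class:`UserModel` on a given study day to the session engine."""

    def __init__(self, model: UserModel, day: int = 1):
        self.model = model
        self.day = day

    # -- calibration epochs -------------------------------------------------

    def zero_trace(self, channel, duration_s, t_start, fs, rng) -> PressureTrace:
        n = round(duration_s * fs)
        t = t_start + np.arange(n) / fs
        noise = self.model.rest_noise_frac * self.model.pmax(channel)
        values = thermal_offset(t, self.model.thermal) + rng.normal(0.0, noise, n)
        return PressureTrace(channel, values, fs=fs, t0=t_start)

    def max_attempt_trace(self, channel, n, t_start, fs, rng):
        """``n`` ramp-hold attempt segments of 2 s each, peaks near Pmax_true."""
        seg_s = 2.0
        m = self.model
        peaks = m.pmax(channel) * (1.0 + m.attempt_var * rng.standard_normal(n))
        peaks = np.maximum(peaks, 0.0)
        seg_n = round(seg_s * fs)
        ramp = np.linspace(0.0, 1.0, seg_n)
        values = np.concatenate([p * ramp for p in peaks])
        t = t_start + np.arange(values.size) / fs
        values = values + thermal_offset(t, m.thermal)
        segments = [
            Window(t_start + i * seg_s, t_start + (i + 1) * seg_s) for i in range(n)
        ]
        return PressureTrace(channel, values, fs=fs, t0=t_start), segments

    # -- tasks ---------------------------------------------------------------

    def tracking_trace(self, cfg: TrackingTaskConfig, pmax, t_start, fs, rng) -> PressureTrace:
        m = self.model
        skill = m.skill(self.day)
        center = 0.5 * (cfg.band.lo + cfg.band.hi) * pmax
        half = 0.5 * (cfg.band.hi - cfg.band.lo) * pmax
        sigma = sigma_for_skill(skill, half) if skill > 0 else 0.0

        n = round(cfg.total_s * fs)
        rel_t = np.arange(n) / fs
        mean = np.zeros(n)
        if skill > 0:
            for phases in build_tracking_schedule(cfg):
                onset = phases.target.start
                # first-order rise during the reaction window; exactly on
                # centre once the scored part begins
                in_target = (rel_t >= onset + m.latency_s) & (rel_t < phases.scored.start)
                rise = 1.0 - np.exp(-(rel_t[in_target] - onset - m.latency_s) / m.approach_tau_s)
                mean[in_target] = center * rise
                scored = (rel_t >= phases.scored.start) & (rel_t < phases.target.end)
                mean[scored] = center
        noise_sd = np.full(n, m.rest_noise_frac * pmax)
        if skill > 0 and np.isfinite(sigma):
            hold = mean > 0
            noise_sd[hold] = max(sigma, 0.0)
        values = mean + rng.normal(0.0, 1.0, n) * noise_sd
        values += thermal_offset(t_start + rel_t, m.thermal)
        return PressureTrace(cfg.channel, values, fs=fs, t0=t_start)

    def breathing_trace(self, cfg: BreathingTaskConfig, pmax, t_start, fs, rng) -> PressureTrace:
        m = self.model
        skill = m.skill(self.day)
        thr = cfg.threshold_frac * pmax
        n = round(cfg.total_s * fs)
        if skill <= 0.0:
            mean, sd = 0.0, m.rest_noise_frac * pmax
        elif skill >= 1.0 - 1e-9:
            mean, sd = 1.5 * thr, 0.0
        else:
            sd = m.breathing_noise_frac * pmax
            mean = thr + sd * stats.norm.ppf(skill)
        values = mean + rng.normal(0.0, 1.0, n) * (sd if sd > 0 else 0.0)
        values += thermal_offset(t_start + np.arange(n) / fs, m.thermal)
        return PressureTrace(cfg.channel, values, fs=fs, t0=t_start)

    # -- games ---------------------------------------------------------------

    def game_controller(self, variant: GameVariant, rng):
        """A cheap bounded random-walk pressure controller for the games."""
        state = {"lip": 0.02, "tongue": 0.02}
        step = 0.004

        def controller(t, game_state) -> GameInput:
            state["lip"] = min(max(state["lip"] + step * rng.standard_normal(), 0.0), 0.12)
            state["tongue"] = min(max(state["tongue"] + step * rng.standard_normal(), 0.0), 0.12)
            return GameInput(state["lip"], state["tongue"])

        return controller


def generate_user_trace(
    user: UserModel,
    cfg: TrackingTaskConfig | BreathingTaskConfig,
    day: int = 1,
    fs: float = 50.0,
    seed: int = 0,
    t_start: float = 0.0,
    corrected: bool = True,
) -> PressureTrace:
    """One task trace for a user on a given day (convenience wrapper).

    With ``corrected=True`` (default) the returned trace is what the device
    sees *after* zero calibration: the thermal baseline term is removed, as
    an in-session zero cal would do.  Pass ``corrected=False`` for the raw
    sensor view; the session engine always works on raw traces and applies
    its own measured zero offsets.
    """
    rng = np.random.default_rng(seed)
    sim = SimulatedUser(user, day)
    if isinstance(cfg, BreathingTaskConfig):
        trace = sim.breathing_trace(cfg, user.pmax(cfg.channel), t_start, fs, rng)
    else:
        trace = sim.tracking_trace(cfg, user.pmax(cfg.channel), t_start, fs, rng)
    if corrected:
        drift = thermal_offset(trace.times, user.thermal)
        trace = replace(trace, values=trace.values - drift)
    return trace


# ---------------------------------------------------------------------------
# Attendance and whole-study simulation


def prescribed_days(weeks: int = 4, sessions_per_week: int = 6) -> list[int]:
    """Study days (1-based) with a prescribed session: the first
    ``sessions_per_week`` days of each week."""
    return [7 * w + d for w in range(weeks) for d in range(1, sessions_per_week + 1)]


def simulate_attendance(
    user: UserModel, weeks: int = 4, sessions_per_week: int = 6, seed: int | np.random.Generator = 0
) -> list[int]:
    """Days actually attended: Bernoulli adherence until geometric dropout.

    This is the exact attendance process :func:`simulate_participant` uses;
    it is exposed separately so compliance properties can be checked
    without paying for full-session simulation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plan_days = set(prescribed_days(weeks, sessions_per_week))
    attended: list[int] = []
    dropped = False
    for day in range(1, 7 * weeks + 1):
        if not dropped and user.dropout_hazard > 0 and rng.random() < user.dropout_hazard:
            dropped = True
        if dropped or day not in plan_days:
            continue
        if rng.random() < user.adherence:
            attended.append(day)
    return attended


def simulate_participant(
    user: UserModel,
    session_config: SessionConfig = SessionConfig(),
    weeks: int = 4,
    sessions_per_week: int = 6,
    seed: int = 0,
    participant_id: str = "sim",
    start_date: str = "2024-01-01",
) -> ParticipantLog:
    """Simulate one participant's whole study: attendance plus full sessions."""
    rng = np.random.default_rng(seed)
    attended = simulate_attendance(user, weeks, sessions_per_week, rng)
    log = ParticipantLog(participant_id, prescribed_days(weeks, sessions_per_week), start_date=start_date)
    for day in attended:
        plan = build_session_plan(session_config, seed=int(rng.integers(0, 2**31 - 1)))
        record = run_session(
            SimulatedUser(user, day),
            plan,
            seed=int(rng.integers(0, 2**31 - 1)),
            participant_id=participant_id,
            day_index=day,
            timestamp=session_date(start_date, day),
        )
        log.sessions.append(record)
    return log


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions for a simulated cohort.

    Skill and adherence parameters are drawn per participant from normal
    distributions (clipped to valid ranges); maximal pressures are
    log-normal.  ``association_rho`` is the programmed Spearman correlation
    between lip-score improvement and the change in supine AHI.
    """

    n: int = 8
    weeks: int = 4
    sessions_per_week: int = 6
    seed: int = 0
    skill0_mean: float = 0.66
    skill0_sd: float = 0.18
    gain_mean: float = 0.21
    gain_sd: float = 0.10
    kappa_days: float = 10.0
    adherence_mean: float = 0.92
    adherence_sd: float = 0.05
    dropout_hazard: float = 0.008
    pmax_tongue_mean: float = 40.0
    pmax_lip_mean: float = 20.0
    pmax_cv: float = 0.2
    ahi_pre_mean: float = 20.7
    ahi_pre_sd: float = 17.8
    supine_factor: float = 1.6
    supine_delta_mean: float = -6.7
    supine_delta_sd: float = 8.0
    ahi_delta_mean: float = -3.0
    ahi_delta_sd: float = 5.0
    association_rho: float = -0.76

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one participant")
        if not -1.0 <= self.association_rho <= 1.0:
            raise ValueError("association_rho must be in [-1, 1]")


def _sample_user(cfg: CohortConfig, rng: np.random.Generator) -> UserModel:
    skill0 = float(np.clip(rng.normal(cfg.skill0_mean, cfg.skill0_sd), 0.05, 0.95))
    gain = float(max(rng.normal(cfg.gain_mean, cfg.gain_sd), 0.0))
    skill_inf = float(min(skill0 + gain, 0.99))
    sigma_ln = math.sqrt(math.log(1.0 + cfg.pmax_cv**2))
    return UserModel(
        pmax_tongue_kpa=float(cfg.pmax_tongue_mean * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)),
        pmax_lip_kpa=float(cfg.pmax_lip_mean * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)),
        skill_0=skill0,
        skill_inf=skill_inf,
        kappa_days=cfg.kappa_days,
        adherence=float(np.clip(rng.normal(cfg.adherence_mean, cfg.adherence_sd), 0.5, 1.0)),
        dropout_hazard=cfg.dropout_hazard,
    )


def _lip_improvement(log: ParticipantLog) -> float:
    """Last-session minus first-session mean lip score (0 if no sessions)."""
    completed = [s for s in log.sessions if s.completed]
    if not completed:
        return 0.0
    def lip_mean(s):
        scores = [t.score_pct for t in s.task_results if t.task_kind.value == "lip"]
        return float(np.mean(scores)) if scores else 0.0
    return lip_mean(completed[-1]) - lip_mean(completed[0])


def generate_covariates(
    cfg: CohortConfig, lip_changes: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Pre/post AHI covariates with a programmed rank association.

    The change in supine AHI is generated through a Gaussian copula on the
    *ranks* of the lip-score improvements, with the latent Pearson
    correlation set to ``2·sin(π·ρ_s/6)`` so the Spearman correlation of
    the output equals ``association_rho`` in expectation (exactly ±1 at the
    extremes, where the copula is a deterministic monotone map).
    """
    n = lip_changes.size
    ranks = stats.rankdata(lip_changes, method="average")
    u = ranks / (n + 1.0)
    rho_s = cfg.association_rho
    if abs(rho_s) >= 1.0 - 1e-12:
        v = 1.0 - u if rho_s < 0 else u
    else:
        r_z = 2.0 * math.sin(math.pi * rho_s / 6.0)
        z_u = stats.norm.ppf(u)
        z_v = r_z * z_u + math.sqrt(1.0 - r_z**2) * rng.standard_normal(n)
        v = stats.norm.cdf(z_v)
    supine_delta = stats.norm.ppf(v, loc=cfg.supine_delta_mean, scale=cfg.supine_delta_sd)

    sigma_ln = math.sqrt(math.log(1.0 + (cfg.ahi_pre_sd / cfg.ahi_pre_mean) ** 2))
    mu_ln = math.log(cfg.ahi_pre_mean) - 0.5 * sigma_ln**2
    ahi_pre = rng.lognormal(mu_ln, sigma_ln, n)
    ahi_post = np.maximum(ahi_pre + rng.normal(cfg.ahi_delta_mean, cfg.ahi_delta_sd, n), 0.0)
    supine_pre = cfg.supine_factor * ahi_pre
    # keep the index non-negative with a *common* shift rather than a
    # per-participant clip: clipping would tie the changes and destroy the
    # programmed rank association at the extremes
    raw_post = supine_pre + supine_delta
    supine_post = raw_post + max(0.0, -float(raw_post.min()))
    return pd.DataFrame(
        {
            "ahi_pre": ahi_pre,
            "ahi_post": ahi_post,
            "ahi_supine_pre": supine_pre,
            "ahi_supine_post": supine_post,
        }
    )


def simulate_cohort(
    cfg: CohortConfig = CohortConfig(), session_config: SessionConfig = SessionConfig()
) -> tuple[list[ParticipantLog], pd.DataFrame]:
    """Simulate a cohort end to end: logs plus a pre/post covariate table.

    Reproducible for a given ``cfg.seed``.  The covariate table has one row
    per participant (indexed by id) and is also copied into each log's
    ``covariates`` mapping.
    """
    rng = np.random.default_rng(cfg.seed)
    logs = []
    for i in range(cfg.n):
        user = _sample_user(cfg, rng)
        logs.append(
            simulate_participant(
                user,
                session_config,
                weeks=cfg.weeks,
                sessions_per_week=cfg.sessions_per_week,
                seed=int(rng.integers(0, 2**31 - 1)),
                participant_id=f"P{i + 1:02d}",
            )
        )
    lip_changes = np.array([_lip_improvement(log) for log in logs])
    covariates = generate_covariates(cfg, lip_changes, rng)
    covariates.insert(0, "participant", [log.participant_id for log in logs])
    covariates = covariates.set_index("participant")
    for log, (_, row) in zip(logs, covariates.iterrows()):
        log.covariates = {k: float(v) for k, v in row.items()}
    return logs, covariates
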