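"""Adherence and efficacy analytics for the 4-week training programme.

Definitions mirror the clinical evaluation:

* **Compliance** — completed sessions divided by the 24 prescribed
  (6 sessions/week × 4 weeks); the pooled cohort figure is total completed
  over total prescribed.
* **Success summary** — per participant, the mean of the 4 task scores of
  a kind in the first and last completed session; group mean and SD across
  participants, with a "96 % CI" reported as mean ± 1.96 SD.  Note this is
  a dispersion band of the raw values, not a standard-error interval; it
  is reported this way deliberately and flagged as such.
* **Association** — Spearman rank correlations with exact permutation
  p-values (all n! permutations when n ≤ 8, seeded Monte-Carlo otherwise).
* **Pre/post inference** — a paired sign-flip permutation test on the mean
  difference.  This is a declared substitute for the original random-
  intercept mixed model, not a replication of its P values.

Game scores are deliberately excluded from all success analytics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .session import ParticipantLog
from .tasks import TaskKind

__all__ = [
    "ComplianceSummary",
    "SuccessSummary",
    "CorrelationResult",
    "compute_compliance",
    "compliance_from_counts",
    "summarize_success",
    "success_summary_from_scores",
    "spearman",
    "permutation_pvalue",
    "paired_permutation_test",
    "build_report",
    "round_half_up",
]

PRESCRIBED_SESSIONS = 24


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, matching printed clinical tables."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Compliance


@dataclass(frozen=True)
class ComplianceSummary:
    per_participant: dict[str, tuple[int, float]]  # id -> (completed, fraction)
    overall_completed: int
    overall_prescribed: int

    @property
    def overall_fraction(self) -> float:
        return self.overall_completed / self.overall_prescribed

    @property
    def overall_pct(self) -> int:
        return int(round_half_up(100.0 * self.overall_fraction))

    @property
    def min_fraction(self) -> float:
        return min(f for _, f in self.per_participant.values())


def compliance_from_counts(
    completed: Mapping[str, int], prescribed: int = PRESCRIBED_SESSIONS
) -> ComplianceSummary:
    """Compliance from per-participant completed-session counts."""
    if not completed:
        raise ValueError("no participants")
    per = {pid: (int(c), int(c) / prescribed) for pid, c in completed.items()}
    return ComplianceSummary(per, sum(c for c, _ in per.values()), prescribed * len(per))


def compute_compliance(logs: Sequence[ParticipantLog]) -> ComplianceSummary:
    """Compliance over participant logs (completed sessions / prescribed)."""
    if not logs:
        raise ValueError("no participant logs")
    if len({log.n_prescribed for log in logs}) != 1:
        raise ValueError("participants have differing prescribed-session counts")
    prescribed = logs[0].n_prescribed
    return compliance_from_counts(
        {log.participant_id: log.n_completed for log in logs}, prescribed
    )


# ---------------------------------------------------------------------------
# Success summaries


@dataclass(frozen=True)
class SuccessSummary:
    """First-day vs last-day group success for one task kind.

    SDs use ddof=1 across participants; ``ci96_*`` is mean ± 1.96 SD — a
    dispersion band of the raw participant values (``dispersion_band`` is
    always True to flag this).
    """

    task_kind: TaskKind
    first_mean: float
    first_sd: float
    last_mean: float
    last_sd: float
    n: int
    dispersion_band: bool = True

    @property
    def ci96_first(self) -> tuple[float, float]:
        return (self.first_mean - 1.96 * self.first_sd, self.first_mean + 1.96 * self.first_sd)

    @property
    def ci96_last(self) -> tuple[float, float]:
        return (self.last_mean - 1.96 * self.last_sd, self.last_mean + 1.96 * self.last_sd)

    @property
    def first_pct(self) -> int:
        return int(round_half_up(self.first_mean))

    @property
    def last_pct(self) -> int:
        return int(round_half_up(self.last_mean))


def success_summary_from_scores(
    first_scores: Sequence[float], last_scores: Sequence[float], task_kind: TaskKind
) -> SuccessSummary:
    first = np.asarray(first_scores, dtype=float)
    last = np.asarray(last_scores, dtype=float)
    if first.size != last.size or first.size < 1:
        raise ValueError("need matching, non-empty first/last score vectors")
    sd = lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0
    return SuccessSummary(
        TaskKind(task_kind), float(first.mean()), sd(first), float(last.mean()), sd(last), first.size
    )


def _day_task_mean(log: ParticipantLog, task_kind: TaskKind, which: str) -> float:
    completed = [s for s in log.sessions if s.completed]
    if not completed:
        raise ValueError(f"participant {log.participant_id} has no completed session")
    session = completed[0] if which == "first" else completed[-1]
    scores = [t.score_pct for t in session.task_results if t.task_kind == task_kind]
    if not scores:
        raise ValueError(f"no {task_kind.value} task in {which} session of {log.participant_id}")
    return float(np.mean(scores))


def summarize_success(logs: Sequence[ParticipantLog], task_kind: TaskKind) -> SuccessSummary:
    """Group success summary for a task kind from participant logs.

    "First day" and "last day" are each participant's first and last
    *completed* session; the per-participant value is the mean of that
    session's task scores of the given kind.
    """
    task_kind = TaskKind(task_kind)
    first = [_day_task_mean(log, task_kind, "first") for log in logs]
    last = [_day_task_mean(log, task_kind, "last") for log in logs]
    return success_summary_from_scores(first, last, task_kind)


# ---------------------------------------------------------------------------
# Rank statistics


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    p_value: float
    n: int
    exact: bool


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank (midrank) tie handling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def _perm_correlations(rx: np.ndarray, ry_perms: np.ndarray) -> np.ndarray:
    """Pearson correlation of centred rank vector ``rx`` with each row of perms."""
    rxc = rx - rx.mean()
    ryc = ry_perms - ry_perms.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rxc) * np.linalg.norm(ryc[0])
    return (ryc @ rxc) / denom


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    two_sided: bool = True,
    seed: int | None = None,
    n_mc: int = 10_000,
    exact_max_n: int = 8,
) -> CorrelationResult:
    """Permutation p-value for the Spearman correlation (or a custom statistic).

    All ``n!`` permutations of ``y`` are enumerated when ``n <= exact_max_n``
    (8! = 40 320); otherwise a seeded Monte-Carlo sample of ``n_mc``
    permutations is drawn.  The p-value is the proportion of permutations —
    the identity included — whose |statistic| reaches the observed
    |statistic| (signed comparison if ``two_sided=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    exact = n <= exact_max_n

    if statistic is None:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = spearman(x, y)
        if exact:
            perms = np.array(list(itertools.permutations(ry)))
        else:
            rng = np.random.default_rng(seed)
            perms = np.array([rng.permutation(ry) for _ in range(n_mc)])
            perms[0] = ry  # include the identity
        vals = _perm_correlations(rx, perms)
    else:
        obs = float(statistic(x, y))
        if exact:
            perms = itertools.permutations(y)
        else:
            rng = np.random.default_rng(seed)
            perms = itertools.chain([tuple(y)], (tuple(rng.permutation(y)) for _ in range(n_mc - 1)))
        vals = np.array([statistic(x, np.asarray(p)) for p in perms])

    tol = 1e-12
    if two_sided:
        count = int(np.count_nonzero(np.abs(vals) >= abs(obs) - tol))
    else:
        count = int(np.count_nonzero(vals >= obs - tol))
    p = count / vals.size
    return CorrelationResult(rs=obs, p_value=p, n=n, exact=exact)


def paired_permutation_test(
    pre: Sequence[float],
    post: Sequence[float],
    seed: int | None = None,
    exact_max_n: int = 20,
    n_mc: int = 10_000,
) -> float:
    """Two-sided sign-flip permutation test on the mean paired difference.

    All ``2^n`` sign assignments are enumerated when ``n <= exact_max_n``;
    otherwise a seeded Monte-Carlo sample is used.  Declared substitute for
    mixed-model pre/post inference, exact under exchangeability of the
    paired differences.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = post - pre
    n = d.size
    obs = abs(d.mean())
    tol = 1e-12
    if n <= exact_max_n:
        total = 0
        count = 0
        chunk = 1 << min(n, 16)
        bits = np.arange(n)
        for start in range(0, 1 << n, chunk):
            codes = np.arange(start, min(start + chunk, 1 << n))[:, None]
            signs = ((codes >> bits) & 1) * 2 - 1
            means = np.abs(signs @ d) / n
            count += int(np.count_nonzero(means >= obs - tol))
            total += codes.size
        return count / total
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_mc - 1, n))
    means = np.abs(signs @ d) / n
    count = 1 + int(np.count_nonzero(means >= obs - tol))  # identity included
    return count / n_mc


# ---------------------------------------------------------------------------
# Report


_COVARIATE_PAIRS = [
    ("ahi", "ahi_pre", "ahi_post"),
    ("ahi_supine", "ahi_supine_pre", "ahi_supine_post"),
    ("ess", "ess_pre", "ess_post"),
]


def _lip_change(log: ParticipantLog) -> float | None:
    completed = [s for s in log.sessions if s.completed]
    if not completed:
        return None
    try:
        first = _day_task_mean(log, TaskKind.LIP, "first")
        last = _day_task_mean(log, TaskKind.LIP, "last")
    except ValueError:
        return None
    return last - first


def build_report(
    logs: Sequence[ParticipantLog], covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Deterministic long-form report table: section, metric, value.

    Sections: compliance; per-task success trajectories (integer-rounded
    percentages, SDs and the ±1.96 SD dispersion band); covariate pre/post
    means to 1 decimal with paired-permutation p; the Spearman association
    of lip-score change with supine-AHI change (exact permutation p).
    Missing covariates simply yield absent rows, never a crash.
    """
    if not logs:
        raise ValueError("no participant logs")
    rows: list[tuple[str, str, float]] = []
    comp = compute_compliance(logs)
    rows.append(("compliance", "overall_pct", comp.overall_pct))
    rows.append(("compliance", "overall_completed", comp.overall_completed))
    rows.append(("compliance", "overall_prescribed", comp.overall_prescribed))
    rows.append(("compliance", "min_participant_pct", round_half_up(100 * comp.min_fraction)))

    for kind in (TaskKind.BREATHING, TaskKind.LIP, TaskKind.TONGUE):
        try:
            s = summarize_success(logs, kind)
        except ValueError:
            continue
        sec = f"success_{kind.value}"
        rows += [
            (sec, "first_day_mean_pct", s.first_pct),
            (sec, "first_day_sd_pct", round_half_up(s.first_sd)),
            (sec, "last_day_mean_pct", s.last_pct),
            (sec, "last_day_sd_pct", round_half_up(s.last_sd)),
            (sec, "ci96_last_lo", round_half_up(s.ci96_last[0], 1)),
            (sec, "ci96_last_hi", round_half_up(s.ci96_last[1], 1)),
        ]

    if covariates is not None and len(covariates):
        for name, pre_col, post_col in _COVARIATE_PAIRS:
            if pre_col not in covariates.columns:
                continue
            pre = covariates[pre_col].to_numpy(float)
            rows.append((f"covariate_{name}", "pre_mean", round_half_up(float(pre.mean()), 1)))
            if post_col in covariates.columns:
                post = covariates[post_col].to_numpy(float)
                rows.append((f"covariate_{name}", "post_mean", round_half_up(float(post.mean()), 1)))
                if pre.size >= 2:
                    rows.append(
                        (f"covariate_{name}", "p_paired_perm", paired_permutation_test(pre, post))
                    )
        if {"ahi_supine_pre", "ahi_supine_post"} <= set(covariates.columns):
            changes = [_lip_change(log) for log in logs]
            if all(c is not None for c in changes) and len(changes) == len(covariates):
                supine_delta = (
                    covariates["ahi_supine_post"] - covariates["ahi_supine_pre"]
                ).to_numpy(float)
                try:
                    res = permutation_pvalue(np.asarray(changes, float), supine_delta)
                    rows.append(("association", "lip_change_vs_supine_ahi_rs", res.rs))
                    rows.append(("association", "p_exact_perm", res.p_value))
                except ValueError:
                    pass

    return pd.DataFrame(rows, columns=["section", "metric", "value"])
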