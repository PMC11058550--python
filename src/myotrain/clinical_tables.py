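"""Bundled clinical-evaluation tables from the device's proof-of-concept study.

Three small CSV fixtures ship with the package:

* ``sessions_completed.csv`` — per-participant completed sessions per week
  of the 4-week programme (8 completers, 6 prescribed sessions/week).
* ``success_rates.csv`` — per-participant tongue and lip success rates (%)
  at baseline (first day) and after training (last day).
* ``ahi_pre_post.csv`` — per-participant apnea-hypopnea index (events/h)
  before and after the programme.

They are the printed group results of the study and serve as ground truth
for the analytics module.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_sessions_completed",
    "load_success_rates",
    "load_ahi_pre_post",
    "session_counts",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("myotrain.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_sessions_completed() -> pd.DataFrame:
    """Weekly completed-session counts, one row per participant."""
    return _load("sessions_completed.csv")


def load_success_rates() -> pd.DataFrame:
    """Baseline and post-training tongue/lip success rates (%), one row per participant."""
    return _load("success_rates.csv")


def load_ahi_pre_post() -> pd.DataFrame:
    """Pre/post apnea-hypopnea index (events/h), one row per participant."""
    return _load("ahi_pre_post.csv")


def session_counts() -> dict[str, int]:
    """Total completed sessions per participant over the 4 weeks."""
    df = load_sessions_completed()
    weeks = [c for c in df.columns if c.startswith("week")]
    return {str(p): int(t) for p, t in zip(df["participant"], df[weeks].sum(axis=1))}
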