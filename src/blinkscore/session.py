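"""Session- and animal-level aggregation of trial classifications.

Percent CR performance is the percentage of counted (non-excluded) paired
trials on which a successful CR occurred; CS-only trials are tallied
separately and never enter the paired denominator. Terminal performance is
the mean over the final three training sessions.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import CR, CS_ONLY, EXCLUDED, PAIRED, SessionSummary, TrialRecord

TERMINAL_SESSIONS = (10, 11, 12)
ROTAROD_MAX_LATENCY_S = 300.0


def summarize_session(
    trials: Sequence[TrialRecord],
    animal_id: str = "",
    strain: str = "C57",
    sex: str = "M",
    session_index: int = 1,
) -> SessionSummary:
    """Aggregate one animal-session's scored trials.

    Counted trials are the non-excluded paired trials; ``percent_cr`` is
    None (absent, not zero) when every paired trial was excluded.
    """
    paired = [t for t in trials if t.trial_type == PAIRED]
    cs_only = [t for t in trials if t.trial_type == CS_ONLY]
    counted = [t for t in paired if t.classification != EXCLUDED]
    n_cr = sum(t.classification == CR for t in counted)
    n_excluded = sum(t.classification == EXCLUDED for t in trials)
    cs_counted = [t for t in cs_only if t.classification != EXCLUDED]
    percent = 100.0 * n_cr / len(counted) if counted else None
    return SessionSummary(
        animal_id=animal_id,
        strain=strain,
        sex=sex,
        session_index=session_index,
        n_counted=len(counted),
        n_cr=n_cr,
        n_excluded=n_excluded,
        percent_cr=percent,
        n_cs_only_counted=len(cs_counted),
        n_cs_only_cr=sum(t.classification == CR for t in cs_counted),
    )


def terminal_performance(summaries: Sequence[SessionSummary]) -> float:
    """Mean percent CR over training sessions 10-12."""
    by_session = {s.session_index: s for s in summaries}
    missing = [i for i in TERMINAL_SESSIONS if i not in by_session]
    if missing:
        raise ValueError(f"missing terminal sessions: {missing}")
    values = [by_session[i].percent_cr for i in TERMINAL_SESSIONS]
    if any(v is None for v in values):
        raise ValueError("terminal session with no counted trials")
    return float(np.mean([v for v in values if v is not None]))


def learning_curve(summaries: pd.DataFrame) -> pd.DataFrame:
    """Group learning curves: mean and SEM of percent CR per session.

    ``summaries`` is tidy with columns animal_id, strain, sex, session_index,
    percent_cr. SEM is NaN (absent) for single-animal groups.
    """
    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan

    out = (
        summaries.dropna(subset=["percent_cr"])
        .groupby(["strain", "sex", "session_index"], observed=True)["percent_cr"]
        .agg(mean="mean", sem=_sem, n="size")
        .reset_index()
    )
    return out


def summaries_to_frame(summaries: Sequence[SessionSummary]) -> pd.DataFrame:
    """Tidy DataFrame view of SessionSummary records."""
    return pd.DataFrame(
        [
            {
                "animal_id": s.animal_id,
                "strain": s.strain,
                "sex": s.sex,
                "session_index": s.session_index,
                "n_counted": s.n_counted,
                "n_cr": s.n_cr,
                "n_excluded": s.n_excluded,
                "percent_cr": s.percent_cr,
                "n_cs_only_counted": s.n_cs_only_counted,
                "n_cs_only_cr": s.n_cs_only_cr,
            }
            for s in summaries
        ]
    )


def rotarod_latencies(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean latency-to-fall per animal per day.

    ``trials`` has columns animal_id, day, latency_s. The accelerating-rod
    protocol bounds a trial at 300 s, so longer latencies are a data error.
    """
    if (trials["latency_s"] > ROTAROD_MAX_LATENCY_S).any():
        bad = trials.loc[trials["latency_s"] > ROTAROD_MAX_LATENCY_S]
        raise ValueError(
            f"latencies exceed the {ROTAROD_MAX_LATENCY_S:.0f} s trial bound: "
            f"{bad['latency_s'].tolist()}"
        )
    if (trials["latency_s"] < 0).any():
        raise ValueError("negative latencies")
    out = (
        trials.groupby(["animal_id", "day"], observed=True)["latency_s"]
        .mean()
        .reset_index(name="mean_latency_s")
    )
    return out
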