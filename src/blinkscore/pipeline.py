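"""End-to-end drivers: simulate -> (render -> extract) -> score -> aggregate.

These glue functions exist so parameter-recovery checks and the analysis
scripts exercise the same code path a real recording would take: synthetic
kinematics are optionally rendered to video frames and re-extracted before
scoring, rather than scored directly.
"""
from __future__ import annotations

import zlib
from dataclasses import replace
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np

from .extraction import extract_trace
from .scoring import score_session
from .session import SessionSummary, summarize_session, terminal_performance
from .synthetic import (
    BlinkKinematicsParams,
    EyeGeometry,
    generate_schedule,
    generate_trace,
    render_video,
)
from .types import CS_ONLY, TrialRecord, TrialSchedule

CrProbability = Union[float, Mapping[int, float], Callable[[int], float]]


def _prob_for_session(cr_probability: CrProbability, session_index: int) -> float:
    if callable(cr_probability):
        return float(cr_probability(session_index))
    if isinstance(cr_probability, Mapping):
        return float(cr_probability[session_index])
    return float(cr_probability)


def simulate_session_records(
    schedule: TrialSchedule,
    params: BlinkKinematicsParams,
    frame_rate_hz: float,
    rng: np.random.Generator,
    via_video: bool = False,
    geometry: EyeGeometry = EyeGeometry(),
) -> list[TrialRecord]:
    """Simulate, optionally render/re-extract, and score one session."""
    trials = []
    for spec in schedule.trials:
        trace = generate_trace(spec, params, frame_rate_hz, rng=rng)
        if via_video:
            stack = render_video(trace, geometry, rng=rng)
            trace = extract_trace(stack)
        trials.append((spec.trial_type, trace))
    return score_session(trials)


def simulate_animal(
    animal_id: str,
    cr_probability: CrProbability,
    seed: int,
    strain: str = "C57",
    sex: str = "M",
    sessions: Sequence[int] = tuple(range(1, 13)),
    params: BlinkKinematicsParams = BlinkKinematicsParams(),
    frame_rate_hz: float = 200.0,
    via_video: bool = False,
    geometry: EyeGeometry = EyeGeometry(),
) -> tuple[list[SessionSummary], dict]:
    """Simulate and score one animal over the given training sessions.

    Returns the per-session summaries plus a ground-truth dict with the
    generator's CR flags per session (for recovery checks) and the scored
    CS-only peak times of the terminal sessions.
    """
    rng = np.random.default_rng(seed)
    n_sessions = max(sessions)
    schedules = generate_schedule(n_sessions, seed=seed)
    summaries = []
    truth_flags: dict[int, list[bool]] = {}
    terminal_peaks: list[float] = []
    for s_idx in sessions:
        schedule = schedules[s_idx - 1]
        p = _prob_for_session(cr_probability, s_idx)
        session_params = replace(params, cr_probability=p)
        records = simulate_session_records(
            schedule, session_params, frame_rate_hz, rng, via_video, geometry
        )
        summaries.append(
            summarize_session(
                records, animal_id=animal_id, strain=strain, sex=sex,
                session_index=s_idx,
            )
        )
        truth_flags[s_idx] = [
            bool(tr.meta.get("cr_present", False))
            for (_t, tr) in _raw_traces(records)
        ]
        if s_idx >= n_sessions - 2:
            terminal_peaks.extend(
                r.peak_time_ms
                for r in records
                if r.trial_type == CS_ONLY and r.peak_time_ms is not None
            )
    truth = {"cr_flags": truth_flags, "terminal_cs_only_peaks_ms": terminal_peaks}
    return summaries, truth


def _raw_traces(records: Sequence[TrialRecord]):
    return [(r.trial_type, r.raw) for r in records]


def simulate_group_terminal_percent_cr(
    n_animals: int,
    cr_probability: float,
    seed: int,
    strain: str = "C57",
    sex: str = "M",
    params: BlinkKinematicsParams = BlinkKinematicsParams(),
    frame_rate_hz: float = 60.0,
    via_video: bool = True,
    geometry: EyeGeometry = EyeGeometry(),
    sessions: Sequence[int] = (10, 11, 12),
) -> dict:
    """Full-pipeline terminal performance of one synthetic group.

    Each animal's terminal sessions are simulated at a constant CR
    probability, rendered to video, re-extracted, scored and aggregated.
    Returns the group mean terminal percent CR and the pooled counted-trial
    total (for binomial error bars).
    """
    group_tag = zlib.crc32(f"{strain}/{sex}".encode()) % (2**31)
    ss = np.random.SeedSequence([seed, group_tag])
    child_seeds = ss.generate_state(n_animals) % (2**31)
    terminal = []
    n_counted = 0
    n_cr = 0
    for i in range(n_animals):
        summaries, _ = simulate_animal(
            f"{strain}_{sex}_{i + 1:02d}",
            cr_probability,
            seed=int(child_seeds[i]),
            strain=strain,
            sex=sex,
            sessions=sessions,
            params=params,
            frame_rate_hz=frame_rate_hz,
            via_video=via_video,
            geometry=geometry,
        )
        terminal.append(terminal_performance(summaries))
        n_counted += sum(s.n_counted for s in summaries)
        n_cr += sum(s.n_cr for s in summaries)
    return {
        "mean_terminal_percent_cr": float(np.mean(terminal)),
        "per_animal": terminal,
        "n_counted": n_counted,
        "n_cr": n_cr,
        "pooled_percent_cr": 100.0 * n_cr / n_counted if n_counted else None,
    }
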