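"""Trial normalization and conditioned-response classification.

Paired (CS-US) trials: the trace within 1500 ms of US onset is normalized
to the range between the signal minimum during the 280 ms after CS onset
and the signal maximum during the 500 ms after US onset. A successful CR
is a normalized signal exceeding 0.15 between 100 and 250 ms after CS
onset; the trial is excluded if the signal exceeds 0.15 before that window.

CS-only trials: the baseline-subtracted trace is normalized to the mean UR
amplitude of the previous 9 paired trials; a CR requires the signal to
exceed 0.15 between 100 and 400 ms while staying below 0.05 between 0 and
99 ms after CS onset.

Window conventions (fixed here for determinism): anchor windows are
half-open on the left, closed on the right — (0, 280] and (US, US+500] ms;
the classification windows are closed as written, [100, 250], [100, 400]
and [0, 99] ms, with the paired exclusion window [0, 100) ms.
"""
from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .types import (
    CR,
    CS_ONLY,
    EXCLUDED,
    NO_CR,
    PAIRED,
    US_ONSET_MS,
    EyelidTrace,
    TrialRecord,
)

CR_THRESHOLD = 0.15
PAIRED_CR_WINDOW_MS = (100.0, 250.0)
CS_ONLY_CR_WINDOW_MS = (100.0, 400.0)
CS_ONLY_BASELINE_WINDOW_MS = (0.0, 99.0)
CS_ONLY_BASELINE_THRESHOLD = 0.05
ANCHOR_CS_SPAN_MS = 280.0
ANCHOR_US_SPAN_MS = 500.0
NORM_HALF_SPAN_MS = 1500.0
#: Centered moving-average span used to smooth CS-only curves for peak time.
PEAK_SMOOTH_MS = 25.0
#: Search window for the smoothed-curve argmax, ms after CS onset.
PEAK_SEARCH_WINDOW_MS = (0.0, 600.0)

DEGENERATE = "degenerate_normalization"
NO_PRECEDING_PAIRED = "no_preceding_paired"


def normalization_anchors(
    raw: EyelidTrace, us_onset_ms: float
) -> tuple[float, float]:
    """(cs_min, us_max): signal min over (0, 280] ms after CS onset and
    signal max over (us_onset, us_onset + 500] ms."""
    t, v = raw.time_ms, raw.value_px
    cs_win = (t > 0.0) & (t <= ANCHOR_CS_SPAN_MS)
    us_win = (t > us_onset_ms) & (t <= us_onset_ms + ANCHOR_US_SPAN_MS)
    if not cs_win.any() or not us_win.any():
        raise ValueError("trace does not cover both normalization anchor windows")
    return float(v[cs_win].min()), float(v[us_win].max())


def normalize_paired(
    raw: EyelidTrace, us_onset_ms: float = US_ONSET_MS
) -> tuple[Optional[np.ndarray], np.ndarray, tuple[float, float]]:
    """Normalize a paired trial's trace onto [~0, ~1] anchor units.

    Returns ``(normalized, time_ms, (cs_min, us_max))`` restricted to the
    window within 1500 ms of US onset. ``normalized`` is None when the
    anchors are degenerate (flat trace, us_max <= cs_min); the caller marks
    such trials excluded rather than propagating NaNs.
    """
    cs_min, us_max = normalization_anchors(raw, us_onset_ms)
    window = np.abs(raw.time_ms - us_onset_ms) <= NORM_HALF_SPAN_MS
    t = raw.time_ms[window]
    if us_max <= cs_min:
        return None, t, (cs_min, us_max)
    norm = (raw.value_px[window] - cs_min) / (us_max - cs_min)
    return norm, t, (cs_min, us_max)


def classify_paired(normalized: np.ndarray, time_ms: np.ndarray) -> str:
    """Apply the CR threshold rule to a normalized paired trial.

    Exclusion takes precedence: any sample above 0.15 in [0, 100) ms
    excludes the trial regardless of what follows.
    """
    lo, hi = PAIRED_CR_WINDOW_MS
    pre = (time_ms >= 0.0) & (time_ms < lo)
    win = (time_ms >= lo) & (time_ms <= hi)
    if not win.any():
        raise ValueError("no samples inside the CR window")
    if np.any(normalized[pre] > CR_THRESHOLD):
        return EXCLUDED
    if np.any(normalized[win] > CR_THRESHOLD):
        return CR
    return NO_CR


def normalize_cs_only(
    raw: EyelidTrace, prev_ur_amplitudes: Sequence[float]
) -> Optional[np.ndarray]:
    """Normalize a CS-only trial by the mean UR of preceding paired trials.

    The trace is baseline-subtracted (mean of the pre-CS samples; the
    minimum over (0, 280] ms if the recording starts at CS onset) and
    divided by the mean of up to the last 9 usable UR amplitudes. Returns
    None when no preceding paired trial is usable.
    """
    amps = [a for a in prev_ur_amplitudes if a > 0][-9:]
    if not amps:
        return None
    t, v = raw.time_ms, raw.value_px
    pre = t < 0.0
    if pre.any():
        baseline = float(v[pre].mean())
    else:
        in_cs = (t > 0.0) & (t <= ANCHOR_CS_SPAN_MS)
        baseline = float(v[in_cs].min())
    return (v - baseline) / float(np.mean(amps))


def classify_cs_only(normalized: np.ndarray, time_ms: np.ndarray) -> str:
    """CR iff the signal exceeds 0.15 in [100, 400] ms and stays below
    0.05 in [0, 99] ms after CS onset."""
    lo, hi = CS_ONLY_CR_WINDOW_MS
    blo, bhi = CS_ONLY_BASELINE_WINDOW_MS
    win = (time_ms >= lo) & (time_ms <= hi)
    base = (time_ms >= blo) & (time_ms <= bhi)
    if not win.any():
        raise ValueError("no samples inside the CS-only CR window")
    if not np.all(normalized[base] < CS_ONLY_BASELINE_THRESHOLD):
        return NO_CR
    if np.any(normalized[win] > CR_THRESHOLD):
        return CR
    return NO_CR


def smooth_trace(values: np.ndarray, time_ms: np.ndarray, span_ms: float) -> np.ndarray:
    """Centered moving average over ``span_ms`` on a regular time grid."""
    if len(time_ms) > 1:
        dt = float(np.mean(np.diff(time_ms)))
        k = max(1, int(round(span_ms / dt)))
        if k % 2 == 0:
            k += 1
    else:
        k = 1
    if k == 1:
        return values.astype(float)
    kernel = np.ones(k) / k
    pad = k // 2
    padded = np.pad(values.astype(float), pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def trial_peak_time(
    normalized: np.ndarray,
    time_ms: np.ndarray,
    smooth_ms: float = PEAK_SMOOTH_MS,
    search_window_ms: tuple[float, float] = PEAK_SEARCH_WINDOW_MS,
) -> float:
    """Peak time of one CS-only CR trial: argmax of the smoothed curve."""
    smoothed = smooth_trace(normalized, time_ms, smooth_ms)
    lo, hi = search_window_ms
    win = (time_ms >= lo) & (time_ms <= hi)
    if not win.any():
        raise ValueError("peak search window contains no samples")
    idx = np.flatnonzero(win)[np.argmax(smoothed[win])]
    return float(time_ms[idx])


def animal_peak_time(trial_peak_times_ms: Sequence[float]) -> Optional[float]:
    """Per-animal peak time: mean over successful CS-only trials of the
    final three sessions; None (metric absent) when there are none."""
    if len(trial_peak_times_ms) == 0:
        return None
    return float(np.mean(trial_peak_times_ms))


def score_trial(
    trial_type: str,
    raw: EyelidTrace,
    us_onset_ms: Optional[float] = None,
    prev_ur_amplitudes: Sequence[float] = (),
) -> TrialRecord:
    """Normalize and classify one trial, producing a full TrialRecord."""
    rec = TrialRecord(trial_type=trial_type, raw=raw, us_onset_ms=us_onset_ms)
    if trial_type == PAIRED:
        us = US_ONSET_MS if us_onset_ms is None else us_onset_ms
        rec.us_onset_ms = us
        norm, t, anchors = normalize_paired(raw, us)
        rec.anchors = anchors
        rec.ur_amplitude = anchors[1] - anchors[0]
        if norm is None:
            rec.classification = EXCLUDED
            rec.exclusion_reason = DEGENERATE
            return rec
        rec.normalized, rec.normalized_time_ms = norm, t
        rec.classification = classify_paired(norm, t)
    elif trial_type == CS_ONLY:
        norm = normalize_cs_only(raw, prev_ur_amplitudes)
        if norm is None:
            rec.classification = EXCLUDED
            rec.exclusion_reason = NO_PRECEDING_PAIRED
            return rec
        rec.normalized, rec.normalized_time_ms = norm, raw.time_ms
        rec.classification = classify_cs_only(norm, raw.time_ms)
        if rec.classification == CR:
            rec.peak_time_ms = trial_peak_time(norm, raw.time_ms)
    else:
        raise ValueError(f"unknown trial_type {trial_type!r}")
    return rec


def score_session(
    trials: Sequence[tuple[str, EyelidTrace]],
) -> list[TrialRecord]:
    """Score a session's trials in order, tracking UR amplitudes so each
    CS-only trial is normalized by the URs of the paired trials before it."""
    ur_history: list[float] = []
    records = []
    for trial_type, raw in trials:
        rec = score_trial(
            trial_type, raw, prev_ur_amplitudes=ur_history
        )
        if trial_type == PAIRED and rec.ur_amplitude and rec.ur_amplitude > 0:
            ur_history.append(rec.ur_amplitude)
        records.append(rec)
    return records
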