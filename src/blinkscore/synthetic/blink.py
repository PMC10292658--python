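"""Synthetic eyelid-closure traces with URs, probabilistic CRs and noise.

The waveform model is deliberately simple — it exists to exercise every
branch of the trial classifier, not to be biomechanically realistic:

* the unconditioned response (UR) is a linear rise starting at US onset,
  peaking after ``ur_rise_ms``, then decaying exponentially;
* a conditioned response (CR), present with probability ``cr_probability``,
  is the same shape scaled to ``cr_amplitude_frac`` of the UR amplitude,
  starting at a Gaussian-sampled latency after CS onset;
* spontaneous blinks are Poisson events with UR-like shape (they trip the
  early-closure exclusion rule when they land before the CR window);
* additive Gaussian pixel noise, clipped so counts stay nonnegative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import CS_DURATION_MS, PAIRED, EyelidTrace, TrialSpec

#: Default camera rate. 200 Hz (5 ms per frame) puts >= 30 frames inside the
#: 100-250 ms CR window; the generator accepts anything down to ~60 Hz.
DEFAULT_FRAME_RATE_HZ = 200.0

#: Recording margin before CS onset and after the last stimulus, ms.
PRE_CS_MS = 500.0
POST_STIM_MS = 1500.0


@dataclass(frozen=True)
class BlinkKinematicsParams:
    """Kinematic and noise parameters of the synthetic eyelid signal.

    All times in ms, amplitudes in white-pixel counts.
    """

    cr_probability: float = 0.5
    cr_onset_mean_ms: float = 160.0
    cr_onset_sd_ms: float = 20.0
    cr_rise_ms: float = 100.0
    cr_amplitude_frac: float = 0.5
    ur_amplitude_px: float = 120.0
    ur_rise_ms: float = 40.0
    decay_tau_ms: float = 250.0
    baseline_px: float = 20.0
    noise_sd_px: float = 2.0
    spontaneous_blink_rate_hz: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.cr_probability <= 1.0:
            raise ValueError("cr_probability must be in [0, 1]")
        if not 0.0 <= self.cr_amplitude_frac <= 1.0:
            raise ValueError("cr_amplitude_frac must be in [0, 1]")
        for name in (
            "cr_onset_mean_ms",
            "cr_onset_sd_ms",
            "cr_rise_ms",
            "ur_amplitude_px",
            "ur_rise_ms",
            "decay_tau_ms",
            "baseline_px",
            "noise_sd_px",
            "spontaneous_blink_rate_hz",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def _blink_shape(
    t_ms: np.ndarray, onset_ms: float, rise_ms: float, amplitude: float, tau_ms: float
) -> np.ndarray:
    """Linear rise to ``amplitude`` over ``rise_ms``, then exponential decay."""
    dt = t_ms - onset_ms
    out = np.zeros_like(t_ms)
    if rise_ms > 0:
        rising = (dt > 0) & (dt <= rise_ms)
        out[rising] = amplitude * dt[rising] / rise_ms
    falling = dt > rise_ms
    if tau_ms > 0:
        out[falling] = amplitude * np.exp(-(dt[falling] - rise_ms) / tau_ms)
    else:
        out[falling] = 0.0
    return out


def generate_trace(
    trial: TrialSpec,
    params: BlinkKinematicsParams,
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> EyelidTrace:
    """Simulate the white-pixel eyelid trace of one trial.

    The trace spans from ``PRE_CS_MS`` before CS onset to ``POST_STIM_MS``
    after US onset (paired) or after CS offset (CS-only). Time is reported
    relative to CS onset. Ground truth — whether a CR was injected and its
    onset/peak times — is stored in ``trace.meta``.
    """
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    end_anchor = trial.us_onset_ms if trial.trial_type == PAIRED else CS_DURATION_MS
    t_end = end_anchor + POST_STIM_MS
    dt = 1000.0 / frame_rate_hz
    if t_end + PRE_CS_MS < dt:
        raise ValueError("trace window shorter than one frame interval")
    # round to the microsecond so window boundaries (100, 250, ... ms)
    # compare exactly when the frame grid lands on them
    t = np.round(np.arange(-PRE_CS_MS, t_end + dt / 2, dt), 6)

    value = np.full_like(t, params.baseline_px)
    meta: dict = {"trial_type": trial.trial_type}

    if trial.trial_type == PAIRED:
        value += _blink_shape(
            t, trial.us_onset_ms, params.ur_rise_ms, params.ur_amplitude_px,
            params.decay_tau_ms,
        )

    cr_present = bool(rng.random() < params.cr_probability)
    meta["cr_present"] = cr_present
    if cr_present:
        onset = params.cr_onset_mean_ms + params.cr_onset_sd_ms * rng.standard_normal()
        onset = max(onset, 0.0)
        amp = params.cr_amplitude_frac * params.ur_amplitude_px
        value += _blink_shape(t, onset, params.cr_rise_ms, amp, params.decay_tau_ms)
        meta["cr_onset_ms"] = float(onset)
        meta["cr_peak_time_ms"] = float(onset + params.cr_rise_ms)

    if params.spontaneous_blink_rate_hz > 0:
        span_s = (t[-1] - t[0]) / 1000.0
        n_spont = rng.poisson(params.spontaneous_blink_rate_hz * span_s)
        for _ in range(n_spont):
            onset = float(rng.uniform(t[0], t[-1]))
            amp = params.ur_amplitude_px * rng.uniform(0.5, 1.0)
            value += _blink_shape(
                t, onset, params.ur_rise_ms, amp, params.decay_tau_ms
            )
        meta["n_spontaneous"] = int(n_spont)

    if params.noise_sd_px > 0:
        value = value + params.noise_sd_px * rng.standard_normal(t.shape)
    value = np.clip(value, 0.0, None)

    return EyelidTrace(
        time_ms=t, value_px=value, frame_rate_hz=frame_rate_hz, meta=meta
    )
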