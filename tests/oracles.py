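"""Independent brute-force oracles used to cross-check the production code.

These deliberately re-derive results by the most literal route available —
per-sample scans of the classification rule text and dense polyline
resampling for circle crossings — and share no code with the implementations
they check.
"""
from __future__ import annotations

import numpy as np


def brute_force_classify_paired(normalized, time_ms) -> str:
    """Scan every sample against the literal CR rule for paired trials."""
    for v, t in zip(normalized, time_ms):
        if 0.0 <= t < 100.0 and v > 0.15:
            return "excluded"
    for v, t in zip(normalized, time_ms):
        if 100.0 <= t <= 250.0 and v > 0.15:
            return "CR"
    return "no_CR"


def brute_force_classify_cs_only(normalized, time_ms) -> str:
    """Scan every sample against the literal CR rule for CS-only trials."""
    for v, t in zip(normalized, time_ms):
        if 0.0 <= t <= 99.0 and not (v < 0.05):
            return "no_CR"
    for v, t in zip(normalized, time_ms):
        if 100.0 <= t <= 400.0 and v > 0.15:
            return "CR"
    return "no_CR"


def dense_resample_sholl(morph, radii_um, step_um=0.01) -> np.ndarray:
    """Circle-crossing counts by dense resampling of every branch polyline.

    Each polyline is resampled at ``step_um`` arclength; a crossing is a
    sign change of (distance-to-soma - r) between consecutive samples.
    """
    center = morph.soma_center
    polylines = []
    for b in morph.branches:
        pts = b.points - center
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        samples = [pts[0]]
        for i in range(len(seg)):
            n = max(1, int(np.ceil(seg_len[i] / step_um)))
            ts = np.arange(1, n + 1) / n
            samples.append(pts[i] + ts[:, None] * seg[i])
        poly = np.vstack(samples)
        polylines.append(np.linalg.norm(poly, axis=1))
    counts = np.zeros(len(radii_um), dtype=int)
    for j, r in enumerate(radii_um):
        c = 0
        for dist in polylines:
            f = dist - r
            c += int(np.sum(f[:-1] * f[1:] < 0))
        counts[j] = c
    return counts
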