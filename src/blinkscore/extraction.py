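"""Eyelid-closure signal extraction from video.

The eye region of each frame is smoothed, thresholded and binarized, and
the number of white pixels — tracking total eyelid closure — is counted per
frame. The time axis is re-referenced so CS onset = 0.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.filters import threshold_otsu

from .types import EyelidTrace, FrameStack

#: Default box-smoothing radius in pixels (kernel side = 2 r + 1).
DEFAULT_SMOOTHING_RADIUS_PX = 2


def extract_trace(
    stack: FrameStack,
    smoothing_radius_px: int = DEFAULT_SMOOTHING_RADIUS_PX,
    binarize_threshold: Optional[float] = None,
    cs_onset_ms: float = 0.0,
) -> EyelidTrace:
    """Smooth, threshold, binarize and count white pixels in the ROI.

    Parameters
    ----------
    stack : FrameStack
        Grayscale frames with strictly increasing timestamps and an eye ROI.
    smoothing_radius_px : int
        Radius of the uniform (box) spatial filter applied per frame.
    binarize_threshold : float, optional
        Intensity cutoff; pixels with smoothed intensity >= threshold are
        white. Defaults to Otsu's threshold computed on the first frame's
        ROI (the habituation frame), so it adapts to the recording's
        illumination without supervision.
    cs_onset_ms : float
        Timestamp of CS onset, subtracted so the output time axis has CS
        onset at 0.

    Returns
    -------
    EyelidTrace
        Per-frame white-pixel counts on the native (unresampled) timestamps.
    """
    x, y, w, h = stack.roi
    if w <= 0 or h <= 0:
        raise ValueError("empty roi")
    roi_frames = stack.frames[:, y : y + h, x : x + w].astype(float)

    if smoothing_radius_px > 0:
        size = 2 * int(smoothing_radius_px) + 1
        roi_frames = uniform_filter(roi_frames, size=(1, size, size), mode="nearest")

    if binarize_threshold is None:
        binarize_threshold = float(threshold_otsu(roi_frames[0]))
    else:
        info: np.iinfo | np.finfo
        if np.issubdtype(stack.frames.dtype, np.integer):
            info = np.iinfo(stack.frames.dtype)
        else:
            info = np.finfo(stack.frames.dtype)
        if not (info.min <= binarize_threshold <= info.max):
            raise ValueError(
                f"threshold {binarize_threshold} outside intensity range of "
                f"{stack.frames.dtype}"
            )

    counts = np.count_nonzero(roi_frames >= binarize_threshold, axis=(1, 2))

    n_frames = len(stack.frames)
    dt = np.diff(stack.timestamps_ms)
    frame_rate = 1000.0 / float(np.mean(dt)) if n_frames > 1 else 0.0
    return EyelidTrace(
        time_ms=stack.timestamps_ms - cs_onset_ms,
        value_px=counts.astype(float),
        frame_rate_hz=frame_rate,
        meta=dict(stack.meta),
    )
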