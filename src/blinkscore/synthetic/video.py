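"""Render eyelid traces as grayscale frame stacks.

Emulates a near-infrared eye camera at the level the downstream analysis
cares about: within the eye ROI the number of bright (lid) pixels is a
monotone, invertible function of the trace value, so smoothing +
thresholding + binarizing + pixel counting recovers the trace up to
quantization. Camera optics are out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import EyelidTrace, FrameStack


@dataclass(frozen=True)
class EyeGeometry:
    """Frame layout for the rendered eye video.

    ``roi`` is (x, y, w, h); lid pixels are drawn row-major inside it so a
    trace value v maps to round(gain * v) bright pixels (clipped to the
    ROI area).
    """

    frame_height: int = 48
    frame_width: int = 64
    roi: tuple[int, int, int, int] = (12, 8, 40, 32)
    lid_intensity: int = 220
    background_intensity: int = 30
    intensity_noise_sd: float = 2.0
    #: bright pixels drawn per unit of trace value; >1 keeps pixel
    #: quantization well below the trace's own noise floor
    gain: float = 4.0

    @property
    def roi_area(self) -> int:
        return self.roi[2] * self.roi[3]


def render_video(
    trace: EyelidTrace,
    geometry: EyeGeometry = EyeGeometry(),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> FrameStack:
    """Render one trial's trace as a grayscale multi-frame stack.

    Frame timestamps are carried through from the trace. Pixel intensities
    get additive Gaussian noise of sd ``geometry.intensity_noise_sd`` (set
    it to 0 for deterministic frames).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    g = geometry
    x, y, w, h = g.roi
    n = len(trace.time_ms)

    n_bright = np.clip(np.rint(g.gain * trace.value_px), 0, g.roi_area).astype(int)
    frames = np.full(
        (n, g.frame_height, g.frame_width), float(g.background_intensity)
    )
    # Row-major fill: pixel k of the ROI is lit iff k < n_bright[frame].
    mask = np.arange(g.roi_area)[None, :] < n_bright[:, None]
    roi_pixels = np.where(mask, float(g.lid_intensity), float(g.background_intensity))
    frames[:, y : y + h, x : x + w] = roi_pixels.reshape(n, h, w)

    if g.intensity_noise_sd > 0:
        frames += g.intensity_noise_sd * rng.standard_normal(frames.shape)
    frames = np.clip(frames, 0, 255).astype(np.uint8)

    return FrameStack(
        frames=frames,
        timestamps_ms=trace.time_ms.copy(),
        roi=g.roi,
        meta=dict(trace.meta),
    )
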