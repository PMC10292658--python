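"""Core domain containers shared across the pipeline.

Times are milliseconds relative to CS onset (CS onset = 0) unless a field
name says otherwise; lengths are micrometres; pixel signals are white-pixel
counts (nonnegative).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Stimulus timing printed in the protocol: a 280 ms light CS co-terminating
#: with a 30 ms corneal airpuff US, so the US starts 250 ms after CS onset.
CS_DURATION_MS = 280.0
US_DURATION_MS = 30.0
US_ONSET_MS = CS_DURATION_MS - US_DURATION_MS

PAIRED = "paired"
CS_ONLY = "cs_only"

CR = "CR"
NO_CR = "no_CR"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial: its type, stimulus times and the ITI before it."""

    trial_type: str  # "paired" | "cs_only"
    cs_onset_ms: float = 0.0
    us_onset_ms: Optional[float] = None  # None for cs_only trials
    iti_s: float = 12.0

    def __post_init__(self) -> None:
        if self.trial_type not in (PAIRED, CS_ONLY):
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.trial_type == PAIRED and self.us_onset_ms is None:
            raise ValueError("paired trials need us_onset_ms")


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered list of trials for one training session."""

    session_index: int
    trials: tuple[TrialSpec, ...]

    def __post_init__(self) -> None:
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class EyelidTrace:
    """Time-stamped eyelid-closure signal for one trial window.

    ``value_px`` is the white-pixel count tracking total eyelid closure;
    ``time_ms`` is relative to CS onset. ``meta`` carries generator ground
    truth (e.g. whether a CR was injected) when the trace is synthetic.
    """

    time_ms: np.ndarray
    value_px: np.ndarray
    frame_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.value_px = np.asarray(self.value_px, dtype=float)
        if self.time_ms.shape != self.value_px.shape:
            raise ValueError("time_ms and value_px must have equal length")
        if np.any(self.value_px < 0):
            raise ValueError("value_px must be nonnegative")


@dataclass
class FrameStack:
    """Ordered grayscale frames with timestamps and an eye ROI.

    ``roi`` is (x, y, w, h) in 0-based pixel coordinates, half-open.
    """

    frames: np.ndarray  # (n, H, W) grayscale
    timestamps_ms: np.ndarray
    roi: tuple[int, int, int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if len(self.timestamps_ms) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_ms) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        x, y, w, h = self.roi
        _, H, W = self.frames.shape
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > W or y + h > H:
            raise ValueError(f"roi {self.roi} outside frame bounds {(H, W)}")


@dataclass
class TrialRecord:
    """One trial's stimuli, trace, normalization, classification and timing."""

    trial_type: str
    raw: EyelidTrace
    cs_duration_ms: float = CS_DURATION_MS
    us_duration_ms: float = US_DURATION_MS
    us_onset_ms: Optional[float] = None
    normalized: Optional[np.ndarray] = None
    normalized_time_ms: Optional[np.ndarray] = None
    classification: Optional[str] = None
    exclusion_reason: Optional[str] = None
    peak_time_ms: Optional[float] = None
    anchors: Optional[tuple[float, float]] = None  # (cs_min, us_max)
    ur_amplitude: Optional[float] = None


@dataclass(frozen=True)
class SessionSummary:
    """Per-animal per-session CR performance on paired (counted) trials."""

    animal_id: str
    strain: str
    sex: str
    session_index: int
    n_counted: int
    n_cr: int
    n_excluded: int
    percent_cr: Optional[float]
    n_cs_only_counted: int = 0
    n_cs_only_cr: int = 0


@dataclass(frozen=True)
class ShollProfile:
    """Intersection counts of the dendritic arbor with circles at fixed steps."""

    radii_um: np.ndarray
    intersections: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii_um", np.asarray(self.radii_um, dtype=float))
        object.__setattr__(
            self, "intersections", np.asarray(self.intersections, dtype=int)
        )
        steps = np.diff(self.radii_um)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("radii must be an arithmetic sequence")
        if np.any(self.intersections < 0):
            raise ValueError("intersection counts must be nonnegative")


@dataclass
class Branch:
    """One dendritic polyline; ``parent`` is the index of the parent branch."""

    points: np.ndarray  # (k, 2) in um
    parent: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("branch needs >= 2 planar points")

    @property
    def length_um(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class Branchlet:
    """Terminal dendritic segment with its measured length and spine count."""

    branchlet_id: int
    length_um: float
    n_spines: int

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("branchlet length must be positive")
        if self.n_spines < 0 or int(self.n_spines) != self.n_spines:
            raise ValueError("spine counts are nonnegative integers")


@dataclass
class NeuronMorphology:
    """Planar Purkinje-like morphology: soma contour plus a dendritic tree."""

    soma_contour: np.ndarray  # (k, 2) closed polygon, um
    soma_center: np.ndarray  # (2,) um
    branches: list[Branch]
    branchlets: list[Branchlet] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.soma_contour = np.asarray(self.soma_contour, dtype=float)
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        if self.soma_center.shape != (2,):
            raise ValueError("soma_center must be a planar point")
        for i, b in enumerate(self.branches):
            if b.parent is not None and not (0 <= b.parent < i):
                raise ValueError("branches must be listed parents-first")

    @property
    def total_branch_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))


@dataclass(frozen=True)
class LobuleMeasurement:
    """One traced layer of one vermal lobule in a midline sagittal section."""

    lobule_id: str  # I/II, III, IV/V, VI, VII, VIII, IX, X
    layer: str  # MCL | GCL | WM
    area_um2: float
    midline_length_um: float
    n_cells: int = 0  # calbindin-positive somata along the layer
    n_folia: int = 0

    LOBULES = ("I/II", "III", "IV/V", "VI", "VII", "VIII", "IX", "X")
    LAYERS = ("MCL", "GCL", "WM")

    def __post_init__(self) -> None:
        if self.lobule_id not in self.LOBULES:
            raise ValueError(f"unknown lobule {self.lobule_id!r}")
        if self.layer not in self.LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.area_um2 < 0 or self.midline_length_um < 0:
            raise ValueError("areas and lengths must be nonnegative")
        if self.n_cells < 0 or self.n_folia < 0:
            raise ValueError("counts must be nonnegative")
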