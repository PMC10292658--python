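"""Cellular and anatomical measurements on traced morphologies and sections.

Implements the Golgi/Nissl-era measurement set: Sholl intersection profiles
at 8 um radial steps, distal spine density with every-seventh-branchlet
sampling, soma cross-sectional area, maximum arbor height, Purkinje-cell
linear density, and layer area/thickness summaries.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from shapely.geometry import Polygon

from .types import LobuleMeasurement, NeuronMorphology, ShollProfile

SHOLL_STEP_UM = 8.0
SPINE_SAMPLING_STRIDE = 7


def _circle_crossings(points: np.ndarray, r: float, skip_start: bool) -> int:
    """Exact number of intersections of one polyline with a circle of
    radius ``r`` centered at the origin.

    Intersections are found per segment by solving the quadratic
    |p1 + t (p2 - p1)|^2 = r^2 for t in [0, 1], mapped to arclength
    positions and deduplicated, so tangencies and vertex-on-circle cases
    count once. ``skip_start`` drops an intersection at the polyline's
    first vertex (used for child branches, whose start is the parent's tip
    and already counted there).
    """
    d = np.diff(points, axis=0)
    seg_len = np.linalg.norm(d, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    positions: list[float] = []
    for i in range(len(d)):
        if seg_len[i] == 0.0:
            continue
        p1 = points[i]
        a = float(d[i] @ d[i])
        b = 2.0 * float(p1 @ d[i])
        c = float(p1 @ p1) - r * r
        disc = b * b - 4.0 * a * c
        if disc < 0.0:
            continue
        sq = np.sqrt(disc)
        for t in ((-b - sq) / (2.0 * a), (-b + sq) / (2.0 * a)):
            if -1e-12 <= t <= 1.0 + 1e-12:
                positions.append(cum[i] + min(max(t, 0.0), 1.0) * seg_len[i])
    if not positions:
        return 0
    tol = max(1e-9 * max(total, 1.0), 1e-9)
    positions.sort()
    deduped = [positions[0]]
    for s in positions[1:]:
        if s - deduped[-1] > tol:
            deduped.append(s)
    if skip_start and deduped and deduped[0] <= tol:
        deduped.pop(0)
    return len(deduped)


def sholl(
    morph: NeuronMorphology,
    step_um: float = SHOLL_STEP_UM,
    max_radius_um: Optional[float] = None,
) -> ShollProfile:
    """Sholl profile: arbor intersections with concentric circles at
    ``step_um`` intervals from the soma center.

    Radii run from ``step_um`` to the largest multiple of ``step_um`` not
    exceeding the arbor's maximal radial extent (or ``max_radius_um``).
    Crossings are computed exactly by segment-circle intersection.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    center = morph.soma_center
    if not np.all(np.isfinite(center)):
        raise ValueError("degenerate soma center")
    rel = [b.points - center for b in morph.branches]
    if max_radius_um is None:
        rmax = max((float(np.linalg.norm(p, axis=1).max()) for p in rel), default=0.0)
    else:
        rmax = float(max_radius_um)
    n_radii = int(np.floor(rmax / step_um + 1e-9))
    radii = step_um * np.arange(1, n_radii + 1)
    counts = np.zeros(len(radii), dtype=int)
    for j, r in enumerate(radii):
        counts[j] = sum(
            _circle_crossings(p, float(r), skip_start=b.parent is not None)
            for p, b in zip(rel, morph.branches)
        )
    return ShollProfile(radii_um=radii, intersections=counts)


def spine_density(
    morph: NeuronMorphology,
    sampling_stride: int = SPINE_SAMPLING_STRIDE,
    seed: int = 0,
    start: Optional[int] = None,
) -> float:
    """Distal spine density, spines per um of sampled branchlet length.

    Every ``sampling_stride``-th branchlet is sampled beginning at a seeded
    random start in {0, ..., stride-1} (or the explicit ``start``); the
    per-cell density is total spines over total length of the sampled
    branchlets, mirroring the unbiased every-seventh-branchlet count.
    """
    if not morph.branchlets:
        raise ValueError("morphology has no branchlets")
    if sampling_stride < 1:
        raise ValueError("sampling_stride must be >= 1")
    if start is None:
        start = int(np.random.default_rng(seed).integers(sampling_stride))
    elif not 0 <= start < sampling_stride:
        raise ValueError("start must be in {0, ..., stride-1}")
    ordered = sorted(morph.branchlets, key=lambda b: b.branchlet_id)
    sampled = ordered[start::sampling_stride]
    if not sampled:
        raise ValueError("sampling selected no branchlets")
    total_spines = sum(b.n_spines for b in sampled)
    total_len = sum(b.length_um for b in sampled)
    return total_spines / total_len


def soma_area(morph: NeuronMorphology) -> float:
    """Cross-sectional soma area in um^2 (planar polygon area)."""
    poly = Polygon(morph.soma_contour)
    if not poly.is_simple or not poly.is_valid:
        raise ValueError("self-intersecting soma contour")
    return float(poly.area)


def arbor_height(morph: NeuronMorphology) -> float:
    """Maximum height of the dendritic arbor in um.

    Height is the maximal perpendicular distance of any branch point from
    the soma-base axis, taken as the horizontal line through the soma
    center (sections are imaged with the pial surface up).
    """
    if not morph.branches:
        return 0.0
    y0 = morph.soma_center[1]
    return float(
        max(np.abs(b.points[:, 1] - y0).max() for b in morph.branches)
    )


def linear_density(m: LobuleMeasurement) -> float:
    """Calbindin-positive cells per 100 um of layer midline length."""
    if m.midline_length_um <= 0:
        raise ValueError("midline_length_um must be positive")
    return 100.0 * m.n_cells / m.midline_length_um


def layer_thickness(m: LobuleMeasurement) -> float:
    """Mean layer thickness in um via the ribbon approximation area/length."""
    if m.midline_length_um <= 0 or m.area_um2 <= 0:
        raise ValueError("area and midline length must be positive")
    return m.area_um2 / m.midline_length_um
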