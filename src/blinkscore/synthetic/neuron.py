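"""Synthetic planar Purkinje-like morphologies with known geometry.

Trees are 2-D, matching the single-plane Sholl and arbor-height measurements
made on Golgi-stained sections. Every branch is stored as an explicit
polyline, so ground-truth circle intersections at any radius are computable
from the stored geometry; branchlet spine counts are Poisson with mean
``spine_density_per_um`` x branchlet length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import Branch, Branchlet, NeuronMorphology


@dataclass(frozen=True)
class SyntheticNeuronParams:
    """Geometry and spine-density parameters of the synthetic tree.

    ``branch_length_mean_um``/``branch_length_sd_um`` parameterize the
    (truncated normal) per-branch length distribution. The dendritic tree
    starts with ``n_primary_branches`` trunks at the soma and bifurcates
    ``branching_depth - 1`` times, growing upward from the soma so the
    arbor reaches roughly ``branching_depth x branch_length_mean_um`` in
    height (Purkinje arbors are strongly polarized).
    """

    n_primary_branches: int = 2
    branch_length_mean_um: float = 45.0
    branch_length_sd_um: float = 10.0
    branching_depth: int = 4
    spine_density_per_um: float = 1.5
    soma_radius_um: float = 9.0
    segments_per_branch: int = 4

    def __post_init__(self) -> None:
        for name in (
            "n_primary_branches",
            "branch_length_mean_um",
            "branch_length_sd_um",
            "branching_depth",
            "spine_density_per_um",
            "soma_radius_um",
            "segments_per_branch",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_primary_branches < 1 or self.branching_depth < 1:
            raise ValueError("need >= 1 primary branch and depth >= 1")


def _soma_contour(center: np.ndarray, radius: float, n: int = 24) -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def _grow_branch(
    start: np.ndarray,
    direction_deg: float,
    length: float,
    n_segments: int,
    rng: np.random.Generator,
    wiggle_deg: float = 12.0,
) -> np.ndarray:
    """A polyline of ``n_segments`` pieces with small angular jitter."""
    pts = [start]
    ang = direction_deg
    seg = length / n_segments
    for _ in range(n_segments):
        ang += rng.normal(0.0, wiggle_deg)
        rad = np.deg2rad(ang)
        pts.append(pts[-1] + seg * np.array([np.cos(rad), np.sin(rad)]))
    return np.asarray(pts)


def generate_morphology(
    params: SyntheticNeuronParams = SyntheticNeuronParams(), seed: int = 0
) -> NeuronMorphology:
    """Generate one seeded planar morphology.

    Branches are listed parents-first; terminal branches become the
    branchlets on which spine counts are drawn.
    """
    rng = np.random.default_rng(seed)
    center = np.zeros(2)
    branches: list[Branch] = []

    # (branch_index, tip, direction, depth) frontier; trunks leave the soma
    # center pointing upward (elevation spread around +90 deg).
    frontier: list[tuple[int, np.ndarray, float, int]] = []
    n0 = params.n_primary_branches
    spread = 70.0 if n0 > 1 else 0.0
    for k in range(n0):
        direction = 90.0 + (0.0 if n0 == 1 else spread * (k / (n0 - 1) - 0.5))
        direction += rng.normal(0.0, 5.0)
        length = _draw_length(params, rng)
        pts = _grow_branch(
            center, direction, length, params.segments_per_branch, rng
        )
        branches.append(Branch(points=pts, parent=None))
        frontier.append((len(branches) - 1, pts[-1], direction, 1))

    while frontier:
        idx, tip, direction, depth = frontier.pop(0)
        if depth >= params.branching_depth:
            continue
        for sign in (-1.0, 1.0):
            child_dir = direction + sign * rng.uniform(18.0, 40.0)
            length = _draw_length(params, rng)
            pts = _grow_branch(
                tip, child_dir, length, params.segments_per_branch, rng
            )
            branches.append(Branch(points=pts, parent=idx))
            frontier.append((len(branches) - 1, pts[-1], child_dir, depth + 1))

    has_child = {b.parent for b in branches if b.parent is not None}
    branchlets = []
    for i, b in enumerate(branches):
        if i not in has_child:
            n_spines = int(
                rng.poisson(params.spine_density_per_um * b.length_um)
            )
            branchlets.append(
                Branchlet(
                    branchlet_id=len(branchlets),
                    length_um=b.length_um,
                    n_spines=n_spines,
                )
            )

    return NeuronMorphology(
        soma_contour=_soma_contour(center, params.soma_radius_um),
        soma_center=center,
        branches=branches,
        branchlets=branchlets,
    )


def _draw_length(params: SyntheticNeuronParams, rng: np.random.Generator) -> float:
    return float(
        max(5.0, rng.normal(params.branch_length_mean_um, params.branch_length_sd_um))
    )


def make_radial_morphology(
    length_um: float, angle_deg: float = 90.0, soma_radius_um: float = 5.0
) -> NeuronMorphology:
    """A degenerate morphology: one straight branch leaving the soma center.

    Useful as an analytic fixture — the branch crosses the circle of radius
    r exactly once for every r < ``length_um``.
    """
    center = np.zeros(2)
    rad = np.deg2rad(angle_deg)
    tip = length_um * np.array([np.cos(rad), np.sin(rad)])
    branch = Branch(points=np.vstack([center, tip]), parent=None)
    return NeuronMorphology(
        soma_contour=_soma_contour(center, soma_radius_um),
        soma_center=center,
        branches=[branch],
        branchlets=[Branchlet(branchlet_id=0, length_um=float(length_um), n_spines=0)],
    )
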