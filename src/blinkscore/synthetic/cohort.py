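"""Synthetic cohorts: tidy per-animal measurements with known group effects.

The generator draws each measurement as

    value = baseline(level) + animal_effect + strain_shift + noise

with a Gaussian per-animal random effect (shared across levels of the
repeated factor, which is what makes repeated-measures ANOVA the right
model downstream) and independent Gaussian residuals. Strain shifts are
applied additively to the BTBR rows of the named measure, so the ground
truth for every group contrast is known exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

STRAINS = ("C57", "BTBR")
SEXES = ("M", "F")

#: Per-group animal counts of the eyeblink-conditioning cohort
#: (C57/BTBR males, C57/BTBR females).
EYEBLINK_DESIGN: dict[tuple[str, str], int] = {
    ("C57", "M"): 13,
    ("BTBR", "M"): 12,
    ("C57", "F"): 10,
    ("BTBR", "F"): 11,
}

LOBULES = ("I/II", "III", "IV/V", "VI", "VII", "VIII", "IX", "X")


@dataclass(frozen=True)
class MeasureSpec:
    """Statistical shape of one synthetic measure.

    ``levels`` is the repeated (within-animal) factor — sessions, lobules,
    layers or Sholl radii — or None for a single value per animal.
    ``baseline`` maps a level to the population mean for C57 animals.
    """

    name: str
    factor2: Optional[str]
    levels: Optional[tuple] = None
    baseline: Callable[[object], float] = lambda level: 0.0
    animal_sd: float = 1.0
    residual_sd: float = 1.0
    lo: Optional[float] = None
    hi: Optional[float] = None


def _learning_curve(session) -> float:
    # Logistic acquisition from ~12% to ~72% CR over 12 sessions.
    s = float(session)
    return 12.0 + 60.0 / (1.0 + np.exp(-(s - 6.0) / 1.8))


def _sholl_bell(radius) -> float:
    # Inverted-U complexity profile peaking ~25 crossings near 70 um.
    r = float(radius)
    return 25.0 * np.exp(-(((r - 70.0) / 55.0) ** 2))


DEFAULT_MEASURES: dict[str, MeasureSpec] = {
    m.name: m
    for m in (
        MeasureSpec(
            "percent_cr", "session", tuple(range(1, 13)),
            _learning_curve, animal_sd=8.0, residual_sd=7.0, lo=0.0, hi=100.0,
        ),
        MeasureSpec(
            "rotarod_latency_s", "day", (1, 2),
            {1: 170.0, 2: 210.0}.__getitem__,
            animal_sd=30.0, residual_sd=25.0, lo=0.0, hi=300.0,
        ),
        MeasureSpec(
            "vermal_area_mm2", None, None, lambda _: 5.4,
            animal_sd=0.35, residual_sd=0.2, lo=0.0,
        ),
        MeasureSpec(
            "layer_area_mm2", "layer", ("MCL", "GCL", "WM"),
            {"MCL": 2.3, "GCL": 1.6, "WM": 0.7}.__getitem__,
            animal_sd=0.15, residual_sd=0.12, lo=0.0,
        ),
        MeasureSpec(
            "linear_density_per_100um", "lobule", LOBULES,
            lambda _: 3.3, animal_sd=0.25, residual_sd=0.3, lo=0.0,
        ),
        MeasureSpec(
            "n_folia", None, None, lambda _: 9.0,
            animal_sd=0.8, residual_sd=0.7, lo=0.0,
        ),
        MeasureSpec(
            "spine_density_per_um", None, None, lambda _: 1.5,
            animal_sd=0.12, residual_sd=0.15, lo=0.0,
        ),
        MeasureSpec(
            "soma_area_um2", None, None, lambda _: 260.0,
            animal_sd=25.0, residual_sd=30.0, lo=0.0,
        ),
        MeasureSpec(
            "sholl_intersections", "radius_um", tuple(range(8, 161, 8)),
            _sholl_bell, animal_sd=2.5, residual_sd=2.0, lo=0.0,
        ),
    )
}


def generate_cohort(
    design: Mapping[tuple[str, str], int] = EYEBLINK_DESIGN,
    effects: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    measures: Optional[Sequence[Union[str, "MeasureSpec"]]] = None,
) -> pd.DataFrame:
    """Generate a tidy cohort table.

    Parameters
    ----------
    design : mapping (strain, sex) -> n animals, each n >= 2.
    effects : mapping measure name -> additive shift applied to BTBR animals
        of that measure (zero for measures not named).
    seed : RNG seed; the table is bit-reproducible given (design, effects, seed).
    measures : subset of measure names, or explicit MeasureSpec objects, to
        generate (default: all built-in measures).

    Returns
    -------
    DataFrame with columns animal_id, strain, sex, measure, factor2, level,
    value — one row per animal x level x measure.
    """
    effects = dict(effects or {})
    if measures is None:
        specs = list(DEFAULT_MEASURES.values())
    else:
        specs = [
            m if isinstance(m, MeasureSpec) else _lookup_measure(m) for m in measures
        ]
    known = set(DEFAULT_MEASURES) | {s.name for s in specs}
    for name in effects:
        if name not in known:
            raise ValueError(
                f"unknown measure {name!r}; known: {sorted(known)}"
            )
    for (strain, sex), n in design.items():
        if strain not in STRAINS or sex not in SEXES:
            raise ValueError(f"unknown design cell {(strain, sex)}")
        if n < 2:
            raise ValueError("need n >= 2 animals per design cell")

    rng = np.random.default_rng(seed)
    rows = []
    for (strain, sex), n in sorted(design.items()):
        for i in range(n):
            animal = f"{strain}_{sex}_{i + 1:02d}"
            for spec in specs:
                shift = effects.get(spec.name, 0.0) if strain == "BTBR" else 0.0
                a_eff = rng.normal(0.0, spec.animal_sd)
                levels = spec.levels if spec.levels is not None else (None,)
                for level in levels:
                    v = spec.baseline(level) + a_eff + shift
                    v += rng.normal(0.0, spec.residual_sd)
                    if spec.lo is not None:
                        v = max(v, spec.lo)
                    if spec.hi is not None:
                        v = min(v, spec.hi)
                    rows.append(
                        (animal, strain, sex, spec.name, spec.factor2, level, v)
                    )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "strain", "sex", "measure", "factor2", "level", "value"],
    )


def _lookup_measure(name: str) -> MeasureSpec:
    try:
        return DEFAULT_MEASURES[name]
    except KeyError:
        raise ValueError(
            f"unknown measure {name!r}; known: {sorted(DEFAULT_MEASURES)}"
        ) from None
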