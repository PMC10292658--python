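# Methods

This note documents the models, conventions and numerical choices behind
`blinkscore`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Trial scoring

**Stimulus frame.** All trial-local times are milliseconds relative to CS
onset. The CS lasts 280 ms; the US lasts 30 ms and co-terminates with the
CS, so US onset is at 250 ms. These are package constants
(`blinkscore.types`), overridable per trial.

**Paired-trial normalization.** The trace within 1500 ms of US onset is
mapped through `(x − cs_min) / (us_max − cs_min)` with `cs_min` the
minimum over (0, 280] ms and `us_max` the maximum over (US, US+500] ms.
The map is invariant to positive affine transforms of the raw signal
(camera gain and offset), which is what makes a pixel-count signal
comparable across trials and animals. A flat trace (`us_max ≤ cs_min`)
cannot be normalized; such trials are marked `excluded` with reason
`degenerate_normalization` rather than propagating NaNs.

**Window conventions.** Stated windows are half-open on the left anchor
where ambiguity exists and closed on the right: anchors (0, 280] and
(US, US+500]; CR windows [100, 250] ms (paired) and [100, 400] ms
(CS-only); the paired exclusion window is [0, 100); the CS-only baseline
window is [0, 99] ms read as an interval (the rule text's wording is
garbled at that point). "Exceeds" is a strict `>`; a single
super-threshold sample counts (no minimum-duration requirement).
Exclusion takes precedence over CR detection.

**CS-only trials.** The trace is baseline-subtracted (mean of pre-CS
samples; if the recording starts at CS onset, the minimum over (0, 280] ms)
and divided by the mean UR amplitude — `us_max − cs_min` — of up to the 9
most recent usable paired trials. Fewer than 9 are averaged when the trial
falls early in the session; none at all marks the trial excluded. A CR
requires the normalized signal to exceed 0.15 in [100, 400] ms *and* stay
below 0.05 throughout [0, 99] ms.

**Peak time.** Per CS-only CR trial: argmax of the normalized curve after
a centered 25 ms moving average, searched over [0, 600] ms (configurable;
the window covers the CR detection range plus the rise-to-peak tail while
keeping late spontaneous blinks from capturing the argmax). Per animal:
the mean over successful CS-only trials of the final three sessions; the
metric is absent, never zero, when no trial qualifies.

**Aggregation.** Percent CR = 100 × CRs / counted paired trials, excluded
trials leaving the denominator; CS-only trials are tallied separately.
Terminal performance is the mean over sessions 10–12; missing sessions are
an error, not an imputation. Rotarod plumbing averages latencies per
animal per day and rejects latencies above the 300 s trial bound.

## Signal extraction

Each frame's eye ROI is smoothed with a uniform box filter (radius 2 px by
default), thresholded, binarized, and its white pixels counted. The
default threshold is Otsu's method on the first frame's ROI, so the
pipeline adapts to illumination without supervision; both radius and
threshold are configurable. Frames are never resampled in time; all
windows are evaluated on native timestamps.

## The synthetic-data generators

The generators define the conditions under which the pipeline is
validated. They are statistical stand-ins, not biophysics.

**Schedules.** 22 blocks × 10 trials per session, 9 paired + 1 CS-only in
a seeded pseudorandom block position; ITI = 12 s + Exp(mean 3 s), so the
protocol's 12 s floor is respected with a realistic spread.

**Eyelid kinematics.** Blinks are linear rises with exponential decays.
The UR rises for 40 ms to `ur_amplitude_px` (default 120 px) from US
onset and decays with τ = 250 ms. A CR is injected with probability
`cr_probability`; its onset is Gaussian (default 160 ± 20 ms after CS
onset), it rises for `cr_rise_ms` = 100 ms to `cr_amplitude_frac` = 0.5 of
the UR amplitude, and decays with the same τ. Spontaneous blinks are
Poisson events (default 0.05 Hz) with UR-like shape — they exist to
exercise the exclusion rule. Additive Gaussian pixel noise (default
sd 2 px) rides on a 20 px baseline; counts are clipped at zero. Ground
truth (CR present, onset, peak time) travels in `trace.meta`. The default
frame rate is 200 Hz so the CR window holds ≥ 30 frames; 60 Hz emulates a
slow camera. Time grids are rounded to 1 µs so frames that nominally land
on a window boundary compare exactly.

With these defaults a detectable crossing happens ~44 ms after CR onset,
so ~1% of injected CRs (onset beyond ~206 ms) cross only after US onset
and are, by the rule's own definition, not countable; recovery checks
against generator flags carry that intrinsic, sub-SE bias.

**Video.** Frames are grayscale with a bright-lid/dark-background eye ROI;
a trace value v lights `round(gain · v)` ROI pixels (gain 4 px per count),
plus Gaussian intensity noise (sd 2). The bright-pixel count is therefore
a monotone, invertible function of the trace, which is all the extraction
method requires; optics, shadows and motion are out of scope. The gain
keeps rendering quantization below the trace's own noise floor — without
it, rank fidelity of the render → extract roundtrip degrades on flat
trace segments.

**Morphologies.** Planar trees (matching single-plane Sholl and height
measurements): `n_primary_branches` trunks leave the soma center growing
upward, each branch a 4-segment polyline with angular jitter, bifurcating
to `branching_depth` levels with per-branch lengths ~N(45, 10²) µm
truncated at 5 µm. Terminal branches are the branchlets; spine counts are
Poisson(`spine_density_per_um` × length). Stored polylines are the exact
geometry, so circle intersections have a computable ground truth.

**Cohorts.** Tidy per-animal tables drawn as
`baseline(level) + animal_effect + strain_shift + noise`, with a Gaussian
per-animal random effect shared across the repeated factor — the
correlation structure that makes repeated-measures ANOVA the right model.
Default measures emulate the study's panels (12-session learning curve,
2-day rotarod, layer/lobule areas, linear density, folia, spine density,
soma area, Sholl counts) with the published group sizes (13/12/10/11 for
eyeblink) as the default design. Strain shifts are additive on BTBR rows,
so every contrast has exact ground truth.

What the generators do *not* emulate: eyelid biomechanics, camera optics,
3-D dendritic geometry, non-Gaussian measurement error, and histology
artifacts. Passing tests therefore certify the analysis logic under known
statistical structure, not performance on real recordings.

## Morphometry

**Sholl.** Radii run 8, 16, 24, … µm up to the arbor's maximal radial
extent. Crossings are computed exactly per polyline segment by solving
|p₁ + t·d|² = r² and collecting roots t ∈ [0, 1] as arclength positions,
deduplicated within 1e-9 of the polyline length — so tangencies and
vertex-on-circle cases count once, deterministically. A child branch
skips a root at its first vertex (its parent's tip already carries it).
The independent check is dense 0.01 µm resampling with sign-change
counting.

**Spine density.** Branchlets are ordered by id; a seeded start
s ∈ {0…6} selects every 7th; density = Σ spines / Σ length of the sample.
For homogeneous counts the estimate is exact for every start; under
Poisson counts its SE is √(density / sampled length).

**Soma, height, sections.** Soma area is the planar polygon area
(self-intersecting contours are a data error). Arbor height is the
maximal |Δy| of any branch vertex from the horizontal axis through the
soma center — sections are assumed imaged pial-side up. Linear density is
100 × cells / layer length (per 100 µm). Layer thickness uses the ribbon
model area / midline length, exact for constant-width ribbons of any
curvature; folia counts are stored and compared, never computed from
images.

## Statistics

Unpaired two-sample t-tests are equal-variance by default (Welch by flag);
two zero-variance groups with equal means return t = 0, p = 1 by
convention. The repeated-measures design uses a mixed (split-plot) ANOVA
— strain between animals, session/lobule/radius within — via pingouin,
with no sphericity correction by default and an explicit error naming the
missing (subject, level) cells of an incomplete design. With a single
within level both ANOVA routes collapse to one-way between-groups ANOVA,
satisfying F = t² exactly. The factorial (non-repeated) two-way ANOVA
treats rows as independent; when animals contribute several levels it is
anticonservative for the between factor — the package keeps that contract
because it mirrors the section-measurement analyses it implements, and
calibrates it only on independent-observation nulls. Bonferroni:
p_adj = min(1, m·p), family defaulting to the comparisons made (one per
level). α = 0.05 throughout; strain effects are reported regardless of
significance.

## Problem sizes and runtime choices

The suite validates at sizes that keep a full run in minutes: classifier–
oracle agreement on 10,000 trials; affine invariance on 1,000; Sholl
exactness on 100 trees; mixed-ANOVA calibration on 500 null cohorts of
6+6 animals; full video-path recovery on 8 animals/group × terminal
sessions 10–12 at 60 Hz with a 48×64 px frame (the rate/size chosen so
the video path stays exercised end to end at cohort scale). The analysis
scripts use 3 animals/group at 100 Hz, trace-level. All RNG flows through
`numpy.random.default_rng` seeds; every generator and pipeline is
bit-reproducible given (params, seed).

## Known limitations

- The scoring thresholds (0.15, 0.05) and windows are protocol constants,
  not fitted; no adaptive or duration-based CR criteria are provided.
- CR amplitude and latency-to-onset metrics are out of scope.
- The Sholl tie-break (count once at tangency/vertex) is one defensible
  convention; counts at exact-tangency radii are measure-zero events for
  real data but matter for constructed fixtures.
- The factorial ANOVA caveat above: per-animal correlation across levels
  inflates its between-factor type-I rate; the repeated-measures route is
  the calibrated one for such designs.
- Real-image steps (ROI selection, manual folia counting, calbindin cell
  detection) are consumed as already-traced measurements, never computed.
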