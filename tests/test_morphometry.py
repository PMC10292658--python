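"""Sholl profiles, spine density, soma area, arbor height, layer metrics."""
import numpy as np
import pytest

from blinkscore.morphometry import (
    arbor_height,
    layer_thickness,
    linear_density,
    sholl,
    soma_area,
    spine_density,
)
from blinkscore.synthetic import (
    SyntheticNeuronParams,
    generate_morphology,
    make_radial_morphology,
)
from blinkscore.types import Branch, Branchlet, LobuleMeasurement, NeuronMorphology

from oracles import dense_resample_sholl


def rotate(morph, angle_deg):
    a = np.deg2rad(angle_deg)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return NeuronMorphology(
        soma_contour=morph.soma_contour @ R.T,
        soma_center=morph.soma_center @ R.T,
        branches=[Branch(points=b.points @ R.T, parent=b.parent) for b in morph.branches],
        branchlets=morph.branchlets,
    )


class TestSholl:
    def test_straight_radial_branch_crosses_each_circle_once(self):
        morph = make_radial_morphology(41.0)
        prof = sholl(morph, step_um=8.0)
        assert np.array_equal(prof.radii_um, [8.0, 16.0, 24.0, 32.0, 40.0])
        assert np.array_equal(prof.intersections, [1, 1, 1, 1, 1])

    def test_empty_arbor_has_no_intersections(self):
        morph = make_radial_morphology(41.0)
        empty = NeuronMorphology(
            soma_contour=morph.soma_contour,
            soma_center=morph.soma_center,
            branches=[],
        )
        prof = sholl(empty, max_radius_um=40.0)
        assert np.all(prof.intersections == 0)

    def test_matches_dense_resampling_oracle_on_random_trees(self):
        for seed in range(12):
            morph = generate_morphology(seed=seed)
            prof = sholl(morph)
            oracle = dense_resample_sholl(morph, prof.radii_um)
            assert np.array_equal(prof.intersections, oracle), f"seed {seed}"

    def test_invariant_under_rigid_rotation(self):
        morph = generate_morphology(seed=3)
        prof0 = sholl(morph)
        prof1 = sholl(rotate(morph, 137.0))
        assert np.array_equal(prof0.intersections, prof1.intersections)

    def test_tangent_segment_counted_once(self):
        # horizontal chord tangent to the r=8 circle at (0, 8)
        branch = Branch(points=np.array([[-5.0, 8.0], [5.0, 8.0]]))
        morph = NeuronMorphology(
            soma_contour=make_radial_morphology(10.0).soma_contour,
            soma_center=np.zeros(2),
            branches=[branch],
        )
        prof = sholl(morph, step_um=8.0)
        assert prof.intersections[0] == 1


class TestSpineDensity:
    def test_single_branchlet_density(self):
        morph = make_radial_morphology(20.0)
        morph.branchlets = [Branchlet(0, length_um=20.0, n_spines=14)]
        assert spine_density(morph, sampling_stride=1) == pytest.approx(0.7)

    def test_homogeneous_density_exact_for_every_start(self):
        branchlets = [
            Branchlet(i, length_um=20.0, n_spines=10) for i in range(21)
        ]
        morph = make_radial_morphology(10.0)
        morph.branchlets = branchlets
        for start in range(7):
            assert spine_density(morph, start=start) == pytest.approx(0.5)

    def test_poisson_recovery_within_three_ses(self):
        params = SyntheticNeuronParams(
            n_primary_branches=4, branching_depth=6, spine_density_per_um=1.0
        )
        morph = generate_morphology(params, seed=9)
        sampled = sorted(morph.branchlets, key=lambda b: b.branchlet_id)[0::7]
        total_len = sum(b.length_um for b in sampled)
        assert total_len >= 500.0
        est = spine_density(morph, start=0)
        se = np.sqrt(1.0 / total_len)  # Poisson rate estimator SE
        assert abs(est - 1.0) < 3 * se

    def test_zero_density_gives_zero_counts(self):
        params = SyntheticNeuronParams(spine_density_per_um=0.0)
        morph = generate_morphology(params, seed=2)
        assert all(b.n_spines == 0 for b in morph.branchlets)
        assert spine_density(morph, seed=0) == 0.0

    def test_no_branchlets_rejected(self):
        morph = make_radial_morphology(10.0)
        morph.branchlets = []
        with pytest.raises(ValueError):
            spine_density(morph, seed=0)


class TestSomaAndHeight:
    def test_square_contour_area(self):
        morph = make_radial_morphology(10.0)
        morph.soma_contour = np.array(
            [[0.0, 0.0], [10.0, 0.0], [10.0, 10.0], [0.0, 10.0]]
        )
        assert soma_area(morph) == pytest.approx(100.0)

    def test_self_intersecting_contour_rejected(self):
        morph = make_radial_morphology(10.0)
        morph.soma_contour = np.array(
            [[0.0, 0.0], [10.0, 10.0], [10.0, 0.0], [0.0, 10.0]]
        )
        with pytest.raises(ValueError):
            soma_area(morph)

    def test_random_convex_polygon_area_matches_monte_carlo(self, rng):
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        pts = np.column_stack([np.cos(ang), np.sin(ang)]) * 10.0
        morph = make_radial_morphology(10.0)
        morph.soma_contour = pts
        exact = soma_area(morph)
        samples = rng.uniform(-10, 10, size=(400_000, 2))
        # point-in-convex-polygon via sign of cross products
        inside = np.ones(len(samples), dtype=bool)
        for i in range(len(pts)):
            a, b = pts[i], pts[(i + 1) % len(pts)]
            inside &= (b[0] - a[0]) * (samples[:, 1] - a[1]) - (b[1] - a[1]) * (
                samples[:, 0] - a[0]
            ) >= 0
        mc = inside.mean() * 400.0
        assert exact == pytest.approx(mc, rel=0.005)

    def test_vertical_branch_height(self):
        morph = make_radial_morphology(150.0, angle_deg=90.0)
        assert arbor_height(morph) == pytest.approx(150.0)

    def test_height_measured_perpendicular_to_soma_base_axis(self):
        morph = make_radial_morphology(100.0, angle_deg=30.0)
        assert arbor_height(morph) == pytest.approx(100.0 * np.sin(np.deg2rad(30.0)))


class TestSectionMeasures:
    def test_linear_density_per_100um(self):
        m = LobuleMeasurement("III", "MCL", area_um2=1.0, midline_length_um=1200.0,
                              n_cells=30)
        assert linear_density(m) == pytest.approx(2.5)

    def test_zero_cells_zero_density(self):
        m = LobuleMeasurement("X", "MCL", area_um2=1.0, midline_length_um=500.0)
        assert linear_density(m) == 0.0

    def test_density_ordering_recovered(self):
        true = {"I/II": 3.6, "VI": 3.0, "X": 2.4}
        ms = [
            LobuleMeasurement(lob, "MCL", area_um2=1.0, midline_length_um=1000.0,
                              n_cells=int(d * 10))
            for lob, d in true.items()
        ]
        est = [linear_density(m) for m in ms]
        assert est == sorted(est, reverse=True)

    def test_thickness_ribbon(self):
        m = LobuleMeasurement("VII", "GCL", area_um2=50_000.0,
                              midline_length_um=1000.0)
        assert layer_thickness(m) == pytest.approx(50.0)

    def test_thickness_scale_invariance(self):
        a = LobuleMeasurement("VII", "GCL", area_um2=50_000.0, midline_length_um=1000.0)
        b = LobuleMeasurement("VII", "GCL", area_um2=100_000.0, midline_length_um=2000.0)
        assert layer_thickness(a) == layer_thickness(b)

    def test_wiggly_ribbon_recovers_width(self):
        # sinusoidal ribbon of constant width w: area/centerline length = w
        w = 40.0
        x = np.linspace(0.0, 2000.0, 2001)
        y = 100.0 * np.sin(2 * np.pi * x / 800.0)
        dy = np.gradient(y, x)
        # unit normals
        nx, ny = -dy / np.hypot(1, dy), 1 / np.hypot(1, dy)
        top = np.column_stack([x + nx * w / 2, y + ny * w / 2])
        bot = np.column_stack([x - nx * w / 2, y - ny * w / 2])[::-1]
        poly = np.vstack([top, bot])
        area = 0.5 * abs(
            np.sum(poly[:, 0] * np.roll(poly[:, 1], -1) - np.roll(poly[:, 0], -1) * poly[:, 1])
        )
        length = np.sum(np.hypot(np.diff(x), np.diff(y)))
        m = LobuleMeasurement("VIII", "MCL", area_um2=float(area),
                              midline_length_um=float(length))
        assert layer_thickness(m) == pytest.approx(w, rel=0.02)

    def test_zero_length_rejected(self):
        m = LobuleMeasurement("IX", "GCL", area_um2=10.0, midline_length_um=0.0)
        with pytest.raises(ValueError):
            linear_density(m)
        with pytest.raises(ValueError):
            layer_thickness(m)
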