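import math

import numpy as np
import pytest
from scipy import integrate

from cochlevol import morphometry as M
from cochlevol.errors import (
    InsufficientTurnsError,
    InvalidInputError,
    InvalidOutlineError,
    SingularGeometryError,
    UndefinedAngleError,
)
from cochlevol.synthetic import generate_spiral_landmarks, generate_window_outline


def circle_path(radius=1.0, turns=1.0, n=100, start="base", z=0.0):
    th = np.linspace(0.0, turns * 2 * math.pi, max(int(n), 8))
    pts = np.column_stack([radius * np.cos(th), radius * np.sin(th),
                           np.full_like(th, z)])
    return M.LandmarkPath(pts, role="spiral", start=start)


def random_rigid(rng):
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] = -q[:, 2]
    return q, rng.uniform(-5, 5, 3)


class TestPolylineLength:
    def test_345_segment(self):
        assert M.polyline_length(np.array([[0, 0, 0], [3, 4, 0]])) == 5.0

    def test_two_unit_segments(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], float)
        assert M.polyline_length(pts) == 2.0

    def test_single_point_rejected(self):
        with pytest.raises(InvalidInputError):
            M.polyline_length(np.array([[0.0, 0.0, 0.0]]))

    def test_spiral_matches_quadrature(self):
        # independent oracle: quadrature of sqrt(r^2 + r'^2) for the
        # planar Archimedean spiral, recomputed here from first principles
        turns, r0, r1 = 2.5, 2.0, 0.8
        n = 600
        th_tot = turns * 2 * math.pi
        k = (r1 - r0) / th_tot
        arc, _ = integrate.quad(
            lambda t: math.sqrt((r0 + k * t) ** 2 + k**2), 0.0, th_tot, limit=200
        )
        path, _ = generate_spiral_landmarks(turns, r0, r1,
                                            points_per_turn=int(n / turns),
                                            seed=5)
        assert M.polyline_length(path) == pytest.approx(arc, rel=0.002)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        path, _ = generate_spiral_landmarks(2.0, 1.5, 0.7, seed=8)
        base = M.polyline_length(path)
        for _ in range(5):
            q, t = random_rigid(rng)
            moved = path.points @ q.T + t
            assert abs(M.polyline_length(moved) - base) < 1e-9


class TestSpiralCenter:
    def test_perfect_circle_exact(self):
        path = circle_path(radius=1.0, n=100)
        g = M.spiral_center(path)
        assert np.linalg.norm(g.center) < 1e-9

    def test_noisy_circle_close(self):
        rng = np.random.default_rng(12)
        path = circle_path(radius=1.0, n=100)
        noisy = M.LandmarkPath(path.points + rng.normal(0, 0.01, path.points.shape),
                               start="base")
        g = M.spiral_center(noisy)
        assert np.linalg.norm(g.center) < 0.02

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises((SingularGeometryError, InvalidInputError)):
            M.spiral_center(M.LandmarkPath(pts, start="base"))

    def test_center_in_plane(self):
        path, _ = generate_spiral_landmarks(2.5, 2.0, 0.8, seed=3)
        g = M.spiral_center(path)
        assert abs((g.center - g.plane_origin) @ g.plane_normal) < 1e-8


class TestTurnCircles:
    def geometry_at_origin(self):
        return M.SpiralGeometry(center=np.zeros(3),
                                plane_normal=np.array([0.0, 0.0, 1.0]),
                                plane_origin=np.zeros(3))

    def test_circle_fixed_center_exact(self):
        path = circle_path(radius=2.0, turns=1.5, n=200)
        r1, r2 = M.fit_turn_circles(path, self.geometry_at_origin())
        assert r1 == pytest.approx(2.0, abs=1e-9)
        assert r2 == pytest.approx(2.0, abs=1e-9)

    def test_piecewise_half_circles(self):
        th1 = np.linspace(0, math.pi, 50)
        th2 = np.linspace(math.pi, 2 * math.pi, 50)
        outer = np.column_stack([2 * np.cos(th2[::-1]), 2 * np.sin(th2[::-1]),
                                 np.zeros(50)])
        inner = np.column_stack([np.cos(th1[::-1]), np.sin(th1[::-1]),
                                 np.zeros(50)])
        path = M.LandmarkPath(np.vstack([outer, inner]), start="base")
        r1, r2 = M.fit_turn_circles(path, self.geometry_at_origin())
        assert r1 == pytest.approx(1.0, abs=1e-9)
        assert r2 == pytest.approx(2.0, abs=1e-9)

    def test_generated_spiral_ratio(self):
        path, truth = generate_spiral_landmarks(2.5, 2.0, 0.8, seed=3)
        g = M.spiral_center(path)
        r1, r2 = M.fit_turn_circles(path, g)
        assert r2 / r1 == pytest.approx(2.5, rel=0.02)

    def test_short_arc_raises(self):
        path = circle_path(radius=1.0, turns=0.6, n=60)
        with pytest.raises(InsufficientTurnsError):
            M.fit_turn_circles(path, self.geometry_at_origin())


class TestCountTurns:
    def geometry_at_origin(self):
        return M.SpiralGeometry(center=np.zeros(3),
                                plane_normal=np.array([0.0, 0.0, 1.0]),
                                plane_origin=np.zeros(3))

    def test_semicircle(self):
        path = circle_path(turns=0.5, n=50)
        assert M.count_turns(path, self.geometry_at_origin()) == pytest.approx(0.5)

    def test_one_and_a_half_revolutions(self):
        path = circle_path(turns=1.5, n=150)
        assert M.count_turns(path, self.geometry_at_origin()) == pytest.approx(1.5)

    def test_generated_spiral(self):
        path, _ = generate_spiral_landmarks(2.7, 2.0, 0.8, points_per_turn=186,
                                            seed=9)
        g = M.spiral_center(path)
        assert M.count_turns(path, g) == pytest.approx(2.7, abs=0.01)

    def test_point_at_center_raises(self):
        pts = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 0], [-1, 0, 0],
                        [0, -1, 0], [1, 0.1, 0]], float)
        with pytest.raises(UndefinedAngleError):
            M.count_turns(M.LandmarkPath(pts, start="base"),
                          self.geometry_at_origin())

    def test_winding_direction_irrelevant(self):
        path = circle_path(turns=1.5, n=150)
        rev = M.LandmarkPath(path.points[::-1].copy(), start="apex")
        g = self.geometry_at_origin()
        assert M.count_turns(path, g) == pytest.approx(M.count_turns(rev, g))


class TestCurvatureGradient:
    def test_equal_radii(self):
        assert M.curvature_gradient(1.0, 1.0) == 1.0

    def test_simple_ratio(self):
        assert M.curvature_gradient(1.0, 2.0) == 2.0

    def test_nonpositive_raises(self):
        with pytest.raises(InvalidInputError):
            M.curvature_gradient(0.0, 1.0)
        with pytest.raises(InvalidInputError):
            M.curvature_gradient(1.0, -2.0)


class TestOvalWindowArea:
    def test_unit_square(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0.5, 1, 0],
                        [0, 1, 0]], float)  # edge midpoint keeps n >= 5
        area = M.oval_window_area(M.LandmarkPath(pts, role="window-outline"))
        assert area == pytest.approx(1.0, abs=1e-12)

    def test_circle_area(self):
        th = np.linspace(0, 2 * math.pi, 360, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th), np.zeros(360)])
        area = M.oval_window_area(M.LandmarkPath(pts, role="window-outline"))
        assert area == pytest.approx(math.pi, rel=1e-3)

    def test_rotated_ellipse_invariance(self):
        th = np.linspace(0, 2 * math.pi, 200, endpoint=False)
        flat = np.column_stack([2 * np.cos(th), np.sin(th), np.zeros(200)])
        a_flat = M.oval_window_area(M.LandmarkPath(flat, role="window-outline"))
        rng = np.random.default_rng(3)
        q, t = random_rigid(rng)
        a_rot = M.oval_window_area(
            M.LandmarkPath(flat @ q.T + t, role="window-outline"))
        assert abs(a_flat - a_rot) < 1e-9

    def test_self_intersection_raises(self):
        bowtie = np.array([[0, 0, 0], [1, 1, 0], [1, 0, 0], [0, 1, 0],
                           [0.0, 0.5, 0]], float)
        with pytest.raises(InvalidOutlineError):
            M.oval_window_area(M.LandmarkPath(bowtie, role="window-outline"))

    def test_too_few_points(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(InvalidInputError):
            M.oval_window_area(M.LandmarkPath(tri, role="window-outline"))


class TestMeasureCochlea:
    def test_planar_circle_analytic(self):
        path = circle_path(radius=1.0, turns=1.5, n=300)
        m = M.measure_cochlea(path)
        assert m.tur == pytest.approx(1.5, abs=1e-6)
        assert m.cur == pytest.approx(1.0, abs=1e-6)
        assert m.ecl == pytest.approx(1.5 * 2 * math.pi, rel=1e-4)
        assert m.recl == pytest.approx(2 * math.pi, rel=1e-4)
        assert m.owa is None

    def test_generated_bundle(self):
        spiral, truth_s = generate_spiral_landmarks(2.5, 2.0, 0.8, seed=3)
        outline, truth_o = generate_window_outline(1.5, 0.9, seed=4)
        m = M.measure_cochlea(spiral, outline)
        assert m.tur == pytest.approx(2.5, abs=0.01)
        assert m.cur == pytest.approx(truth_s.params["cur"], rel=0.02)
        assert m.ecl == pytest.approx(truth_s.params["arc_length"], rel=0.002)
        assert m.owa == pytest.approx(truth_o.params["area"], rel=1e-3)

    def test_recl_uses_unrounded_values(self):
        spiral, _ = generate_spiral_landmarks(2.47, 2.0, 0.8, seed=6)
        m = M.measure_cochlea(spiral)
        assert m.recl == pytest.approx(m.ecl / m.tur, rel=1e-12)

    def test_rounded_reporting(self):
        m = M.CochlearMeasurements(ecl=31.25, tur=2.35, cur=5.55, recl=13.2978,
                                   owa=3.14159)
        r = m.rounded()
        assert r["ECL"] == 31.3 and r["TUR"] == 2.4 and r["CUR"] == 5.6
        assert r["RECL"] == 13.3 and r["OWA"] == 3.14


class TestInvariants:
    def test_scaling_laws(self):
        spiral, _ = generate_spiral_landmarks(2.5, 2.0, 0.8, seed=3)
        outline, _ = generate_window_outline(1.5, 0.9, seed=4)
        m1 = M.measure_cochlea(spiral, outline)
        s = 3.7
        m2 = M.measure_cochlea(
            M.LandmarkPath(spiral.points * s, start=spiral.start),
            M.LandmarkPath(outline.points * s, role="window-outline"),
        )
        assert m2.tur == pytest.approx(m1.tur, rel=1e-9)
        assert m2.cur == pytest.approx(m1.cur, rel=1e-9)
        assert m2.ecl == pytest.approx(m1.ecl * s, rel=1e-9)
        assert m2.owa == pytest.approx(m1.owa * s * s, rel=1e-9)

    def test_path_reversal(self):
        spiral, _ = generate_spiral_landmarks(2.5, 2.0, 0.8, seed=3)
        m1 = M.measure_cochlea(spiral)
        m2 = M.measure_cochlea(spiral.reversed())
        assert m2.ecl == pytest.approx(m1.ecl, rel=1e-12)
        assert m2.tur == pytest.approx(m1.tur, rel=1e-9)
        assert m2.cur == pytest.approx(m1.cur, rel=1e-9)

    def test_round_half_away(self):
        assert M.round_half_away(0.25, 1) == 0.3
        assert M.round_half_away(-0.25, 1) == -0.3
        assert M.round_half_away(2.5) == 3.0
        assert M.round_half_away(3.135, 2) == 3.14
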