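"""Geometric primitives: registration, ray casting, Bezier evaluation."""

import numpy as np
import pytest
import trimesh

from channelmill.geometry import (
    BezierSegment,
    CompositePath,
    DegenerateConfigurationError,
    RigidTransform,
    SurfaceMesh,
    ray_intersect,
    rigid_register,
)


def random_transform(rng):
    axis = rng.normal(size=3)
    return RigidTransform.from_axis_angle(
        axis / np.linalg.norm(axis), rng.uniform(-np.pi, np.pi), rng.uniform(-10, 10, 3)
    )


class TestRigidRegister:
    def test_identity(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        t, res = rigid_register(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        assert res < 1e-12

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(0)
        src = rng.uniform(-5, 5, (4, 3))
        t = RigidTransform.from_axis_angle([0, 0, 1], np.pi / 2, [1, 2, 3])
        rec, res = rigid_register(src, t.apply(src))
        assert np.allclose(rec.rotation, t.rotation, atol=1e-9)
        assert np.allclose(rec.translation, t.translation, atol=1e-9)
        assert res < 1e-9

    def test_noise_residual_scale(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(-10, 10, (8, 3))
        residuals = []
        for _ in range(100):
            dst = src + rng.normal(0, 0.05, src.shape)
            _, res = rigid_register(src, dst)
            residuals.append(res)
        assert 0.02 < np.mean(residuals) < 0.08

    def test_inverse_property(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-5, 5, (6, 3))
        for _ in range(100):
            t = random_transform(rng)
            rec, _ = rigid_register(t.apply(pts), pts)
            inv = t.inverse()
            assert np.allclose(rec.rotation, inv.rotation, atol=1e-9)
            assert np.allclose(rec.translation, inv.translation, atol=1e-9)

    @pytest.mark.parametrize(
        "src",
        [
            np.array([[0, 0, 0], [1, 0, 0]], dtype=float),
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float),
        ],
        ids=["too_few", "collinear"],
    )
    def test_degenerate_configurations(self, src):
        with pytest.raises(DegenerateConfigurationError):
            rigid_register(src, src)


@pytest.fixture(scope="module")
def cube():
    return SurfaceMesh.from_trimesh(trimesh.creation.box(extents=(1, 1, 1)))


class TestRayCasting:
    def test_cube_center_hit(self, cube):
        hit = ray_intersect(cube, [0, 0, 0], [1, 0, 0])
        assert hit is not None
        assert np.allclose(hit.point, [0.5, 0, 0], atol=1e-12)
        assert hit.distance == pytest.approx(0.5)

    def test_miss_returns_none(self, cube):
        assert ray_intersect(cube, [5, 0, 0], [1, 0, 0]) is None

    def test_sphere_distances_match_analytic(self):
        sphere = SurfaceMesh.from_trimesh(trimesh.creation.icosphere(3, 2.0))
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            hit = ray_intersect(sphere, [0, 0, 0], d)
            assert hit is not None
            # the faceted surface lies slightly inside the analytic sphere
            assert 2.0 - 0.01 <= hit.distance <= 2.0 + 1e-9


class TestBezier:
    def test_collinear_control_points_have_zero_curvature(self):
        seg = BezierSegment([[0, 0, 0], [1, 0, 0], [2, 0, 0], [4, 0, 0]])
        t = np.linspace(0, 1, 50)
        assert np.all(seg.curvature(t) < 1e-12)

    def test_endpoint_interpolation(self):
        rng = np.random.default_rng(4)
        cp = rng.uniform(-3, 3, (4, 3))
        seg = BezierSegment(cp)
        assert np.allclose(seg.evaluate(0.0), cp[0], atol=1e-14)
        assert np.allclose(seg.evaluate(1.0), cp[3], atol=1e-14)

    def test_arc_fit_curvature(self):
        # tangent-constrained cubic fit of a 90-degree arc of radius 5 mm
        seg = arc_cubic(
            np.array([5.0, 0.0, 0.0]), np.array([0.0, 5.0, 0.0]),
            np.array([0.0, 0.0, 0.0]), 5.0,
        )
        tt = np.linspace(0.1, 0.9, 50)
        assert np.allclose(seg.curvature(tt), 0.2, rtol=0.01)

    def test_curvature_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seg = BezierSegment(rng.uniform(-5, 5, (4, 3)))
            t = rng.uniform(0.1, 0.9, 10)
            h = 1e-5
            d1 = (seg.evaluate(t + h) - seg.evaluate(t - h)) / (2 * h)
            d2 = (seg.evaluate(t + h) - 2 * seg.evaluate(t) + seg.evaluate(t - h)) / h**2
            num = np.linalg.norm(np.cross(d1, d2), axis=-1)
            den = np.linalg.norm(d1, axis=-1) ** 3
            fd = np.where(den > 1e-12, num / np.where(den == 0, 1, den), 0.0)
            assert np.allclose(seg.curvature(t), fd, atol=1e-5, rtol=1e-4)


def arc_cubic(p0, p1, center, radius):
    """Standard cubic approximation of a circular arc."""
    a0 = np.arctan2(p0[1] - center[1], p0[0] - center[0])
    a1 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
    phi = a1 - a0
    k = (4.0 / 3.0) * np.tan(phi / 4.0) * radius
    t0 = np.array([-np.sin(a0), np.cos(a0), 0.0])
    t1 = np.array([-np.sin(a1), np.cos(a1), 0.0])
    return BezierSegment(np.array([p0, p0 + k * t0, p1 - k * t1, p1]))


class TestArcLength:
    def test_straight_segment(self):
        seg = BezierSegment([[0, 0, 0], [3, 0, 0], [7, 0, 0], [10, 0, 0]])
        assert CompositePath([seg]).arc_length() == pytest.approx(10.0, abs=1e-6)

    def test_semicircle(self):
        c = np.array([0.0, 0.0, 0.0])
        p0 = np.array([5.0, 0.0, 0.0])
        pm = np.array([0.0, 5.0, 0.0])
        p1 = np.array([-5.0, 0.0, 0.0])
        path = CompositePath([arc_cubic(p0, pm, c, 5.0), arc_cubic(pm, p1, c, 5.0)])
        assert path.arc_length() == pytest.approx(np.pi * 5.0, rel=1e-3)

    def test_additivity(self):
        rng = np.random.default_rng(6)
        cp1 = rng.uniform(-3, 3, (4, 3))
        cp2 = np.vstack([cp1[3], rng.uniform(-3, 3, (3, 3))])
        path = CompositePath([BezierSegment(cp1), BezierSegment(cp2)])
        parts = sum(seg.arc_length() for seg in path.segments)
        assert path.arc_length() == pytest.approx(parts, abs=1e-12)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(7)
        seg = BezierSegment(rng.uniform(-4, 4, (4, 3)))
        path = CompositePath([seg])
        base = path.arc_length()
        for _ in range(20):
            t = random_transform(rng)
            assert path.transformed(t).arc_length() == pytest.approx(base, abs=1e-9)


class TestRigidTransform:
    def test_compose_and_inverse_closed(self):
        rng = np.random.default_rng(8)
        a, b = random_transform(rng), random_transform(rng)
        pts = rng.uniform(-5, 5, (10, 3))
        assert np.allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12)
        ident = a.compose(a.inverse())
        assert np.allclose(ident.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(ident.translation, 0, atol=1e-12)

    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
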