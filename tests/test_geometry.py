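"""Geometric primitives: projections, frames, Cardan decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afmkin.errors import InvalidGeometryError
from afmkin.geometry import (
    Frame,
    angle_between,
    build_frame,
    cardan_zxy,
    compose_cardan_zxy,
    planar_orientation_error,
    project_point_on_plane,
    rot_axis,
)

finite = st.floats(-1e3, 1e3, allow_nan=False)
vec = st.tuples(finite, finite, finite).map(np.array)


class TestProjection:
    def test_axis_aligned_plane(self):
        out = project_point_on_plane((3, 4, 7), (0, 0, 1), (0, 0, 0))
        np.testing.assert_allclose(out, [3, 4, 0], atol=1e-12)

    def test_point_on_plane_unchanged(self):
        p = np.array([1.0, 2.0, 0.0])
        np.testing.assert_allclose(project_point_on_plane(p, (0, 0, 5), (9, -3, 0)), p)

    def test_zero_normal_rejected(self):
        with pytest.raises(InvalidGeometryError):
            project_point_on_plane((1, 2, 3), (0, 0, 0), (0, 0, 0))

    @given(p=vec, n=vec, q=vec)
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form(self, p, n, q):
        if np.linalg.norm(n) < 1e-6:
            return
        out = project_point_on_plane(p, n, q)
        nh = n / np.linalg.norm(n)
        expected = p - np.dot(p - q, nh) * nh  # independent closed form
        np.testing.assert_allclose(out, expected, atol=1e-9)
        # result lies on the plane; residual parallel to the normal
        assert abs(np.dot(out - q, nh)) < 1e-6
        assert np.linalg.norm(np.cross(p - out, nh)) < 1e-6 * (1 + np.linalg.norm(p - out))


class TestBuildFrame:
    def test_identity(self):
        f = build_frame((0, 0, 0), (1, 0, 0), (0, 1, 0), "x", "y")
        np.testing.assert_allclose(f.rotation, np.eye(3), atol=1e-12)

    def test_scale_and_shear_invariance(self):
        a = build_frame((0, 0, 0), (2, 0, 0), (1, 1, 0), "x", "y")
        b = build_frame((0, 0, 0), (1, 0, 0), (0, 1, 0), "x", "y")
        np.testing.assert_allclose(a.rotation, b.rotation, atol=1e-12)

    def test_parallel_inputs_rejected(self):
        with pytest.raises(InvalidGeometryError, match="parallel"):
            build_frame((0, 0, 0), (1, 0, 0), (2, 0, 0), "x", "y")

    @pytest.mark.parametrize("labels", [("x", "y"), ("y", "x"), ("x", "z"),
                                        ("z", "x"), ("y", "z"), ("z", "y")])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_orthonormal_right_handed_primary_aligned(self, labels, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=3)
        s = rng.normal(size=3)
        if np.linalg.norm(np.cross(p, s)) < 1e-3:
            s = s + np.array([0.0, 1.0, 0.0])
        f = build_frame(rng.normal(size=3), p, s, *labels)
        R = f.rotation
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        idx = "xyz".index(labels[0])
        np.testing.assert_allclose(R[:, idx], p / np.linalg.norm(p), atol=1e-9)
        # secondary axis lies in the span of the two inputs
        k = 3 - idx - "xyz".index(labels[1])
        assert abs(np.dot(R[:, k], p)) < 1e-9
        assert abs(np.dot(R[:, k], s)) < 1e-9 * np.linalg.norm(s)


class TestCardan:
    def test_identical_rotations_zero(self):
        R = rot_axis("z", 33.0) @ rot_axis("x", -12.0)
        assert cardan_zxy(R, R) == pytest.approx((0, 0, 0), abs=1e-10)

    def test_single_axis_sagittal(self):
        prox = np.eye(3)
        assert cardan_zxy(prox, rot_axis("z", 10.0)) == pytest.approx((10, 0, 0), abs=1e-10)

    def test_single_axis_frontal_and_transverse(self):
        assert cardan_zxy(np.eye(3), rot_axis("x", 1.5)).frontal == pytest.approx(1.5, abs=1e-10)
        assert cardan_zxy(np.eye(3), rot_axis("y", -7.0)).transverse == pytest.approx(-7.0, abs=1e-10)

    def test_known_triplet_round_trip(self):
        out = cardan_zxy(np.eye(3), compose_cardan_zxy(12.0, -7.0, 4.0))
        assert out == pytest.approx((12.0, -7.0, 4.0), abs=1e-10)

    def test_round_trip_dense_grid(self):
        """compose then decompose is the identity on (-90, 90)^3."""
        angles = np.linspace(-85, 85, 7)
        worst = 0.0
        for a in angles:
            for b in angles:
                for c in angles:
                    out = cardan_zxy(np.eye(3), compose_cardan_zxy(a, b, c))
                    worst = max(worst, np.max(np.abs(np.subtract(out, (a, b, c)))))
        assert worst < 1e-8

    def test_round_trip_with_random_proximal(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            prox = compose_cardan_zxy(*rng.uniform(-170, 170, 3))
            abg = rng.uniform(-85, 85, 3)
            dist = prox @ compose_cardan_zxy(*abg)
            np.testing.assert_allclose(cardan_zxy(prox, dist), abg, atol=1e-8)

    def test_gimbal_convention(self):
        """At |frontal| = 90 deg the transverse angle is zero by convention
        and recomposition still reproduces the relative rotation."""
        rel = compose_cardan_zxy(25.0, 90.0, 0.0)
        out = cardan_zxy(np.eye(3), rel)
        assert out.gimbal
        assert out.transverse == 0.0
        np.testing.assert_allclose(compose_cardan_zxy(*out), rel, atol=1e-8)


class TestAngleBetween:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 0, 0), (1, 1, 0), 45.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
    ])
    def test_known_values(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-9)

    def test_matches_acos_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            u, v = rng.normal(size=(2, 3))
            expected = np.degrees(np.arccos(np.clip(
                np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v), -1, 1)))
            assert angle_between(u, v) == pytest.approx(expected, abs=1e-6)

    @given(u=vec, v=vec, s=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_and_scale_invariant(self, u, v, s):
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        assert angle_between(u, v) == pytest.approx(angle_between(v, u), abs=1e-9)
        assert angle_between(s * u, v) == pytest.approx(angle_between(u, v), abs=1e-7)

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidGeometryError):
            angle_between((0, 0, 0), (1, 0, 0))


class TestPlanarOrientationError:
    def test_identical_zero(self):
        R = compose_cardan_zxy(9.0, 4.0, -3.0)
        assert planar_orientation_error(R, R) == pytest.approx((0, 0, 0), abs=1e-10)

    def test_single_axis_frontal(self):
        R = compose_cardan_zxy(20.0, -5.0, 12.0)
        err = planar_orientation_error(R, R @ rot_axis("x", 1.5))
        assert err.frontal == pytest.approx(1.5, abs=1e-9)
        assert abs(err.sagittal) < 1e-9 and abs(err.transverse) < 1e-9

    @pytest.mark.parametrize("axis,theta", [("z", 30.0), ("x", 30.0), ("y", -30.0),
                                            ("z", -1e-3), ("x", 5.0)])
    def test_single_axis_any_plane_exact(self, axis, theta):
        R = compose_cardan_zxy(-14.0, 6.0, 40.0)
        err = planar_orientation_error(R, R @ rot_axis(axis, theta))
        plane = {"z": "sagittal", "x": "frontal", "y": "transverse"}[axis]
        assert getattr(err, plane) == pytest.approx(theta, abs=1e-8)

    def test_small_rotation_matches_projection_oracle(self):
        """For rotations < 5 deg each plane angle agrees with the angle of
        the rotated axes projected into the reference planes."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            ref = compose_cardan_zxy(*rng.uniform(-40, 40, 3))
            # the two decompositions agree to second order, so keep the
            # total rotation below ~3 deg for the 0.05 deg agreement bound
            small = compose_cardan_zxy(*rng.uniform(-1.7, 1.7, 3))
            test = ref @ small
            err = planar_orientation_error(ref, test)
            rel = ref.T @ test
            x, y = rel[:, 0], rel[:, 1]
            sag = np.degrees(np.arctan2(x[1], x[0]))        # x projected on x-y
            fro = np.degrees(np.arctan2(y[2], y[1]))        # y projected on y-z
            tra = np.degrees(np.arctan2(-x[2], x[0]))       # x projected on x-z
            assert err.sagittal == pytest.approx(sag, abs=0.05)
            assert err.frontal == pytest.approx(fro, abs=0.05)
            assert err.transverse == pytest.approx(tra, abs=0.05)


class TestFrame:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(InvalidGeometryError):
            Frame(np.zeros(3), np.eye(3) * 1.01)

    def test_lab_local_round_trip(self):
        f = Frame(np.array([1.0, 2.0, 3.0]), compose_cardan_zxy(30.0, 10.0, -5.0))
        p = np.array([4.0, -5.0, 6.0])
        np.testing.assert_allclose(f.to_local(f.to_lab(p)), p, atol=1e-12)
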