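"""Rigid transforms, ICP and the two-stage deviation maps."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from leafmotion.cloud import PointCloud
from leafmotion.registration import (
    DeviationMap,
    RigidTransform,
    apply_transform,
    chamfer_deviation,
    deviation_summary,
    icp_rigid,
    quadric_refined_deviation,
)


def rot_z(deg: float) -> np.ndarray:
    a = np.radians(deg)
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]
    )


@pytest.fixture
def blob():
    return PointCloud(np.random.default_rng(4).normal(0, 0.1, (300, 3)))


class TestRigidTransform:
    def test_rejects_non_orthonormal(self):
        with pytest.raises(ValueError):
            RigidTransform(np.eye(3) * 1.1, np.zeros(3))

    def test_rejects_reflection(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_inverse_composition(self, blob):
        t = RigidTransform(rot_z(25.0), [0.1, -0.2, 0.05])
        back = apply_transform(apply_transform(blob, t), t.inverse())
        assert np.allclose(back.points, blob.points, atol=1e-12)

    def test_isometry(self, blob):
        t = RigidTransform(rot_z(73.0), [1.0, 2.0, 3.0])
        moved = apply_transform(blob, t)
        d0 = cdist(blob.points[:40], blob.points[:40])
        d1 = cdist(moved.points[:40], moved.points[:40])
        assert np.allclose(d0, d1, atol=1e-12)

    def test_matrix_round_trip(self):
        t = RigidTransform(rot_z(10.0), [0.1, 0.0, 0.3])
        t2 = RigidTransform.from_matrix(t.matrix())
        assert np.allclose(t.rotation, t2.rotation)
        assert np.allclose(t.translation, t2.translation)

    def test_identity_preserves_attrs(self, blob):
        blob.attrs["intensity"] = np.arange(float(len(blob)))
        out = apply_transform(blob, RigidTransform.identity())
        assert np.array_equal(out.points, blob.points)
        assert "intensity" in out.attrs


class TestICP:
    def test_identity_case(self, blob):
        t, resid, _ = icp_rigid(blob, blob)
        assert resid < 1e-9
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_translation(self, blob):
        moved = apply_transform(blob, RigidTransform(np.eye(3), [0.05, 0, 0]))
        t, _, _ = icp_rigid(moved, blob)
        assert np.allclose(t.translation, [-0.05, 0, 0], atol=1e-6)
        assert t.rotation_angle_deg() < 1e-4

    def test_recovers_rotation_about_centroid(self, blob):
        c = blob.points.mean(axis=0)
        R = rot_z(10.0)
        moved = PointCloud((blob.points - c) @ R.T + c)
        t, _, _ = icp_rigid(moved, blob)
        assert abs(t.rotation_angle_deg() - 10.0) < 0.01


class TestChamfer:
    def test_self_deviation_is_zero(self, blob):
        dev = chamfer_deviation(blob, blob)
        assert np.all(dev.distances == 0.0)

    def test_plane_offset_along_normal(self):
        xs = np.arange(0, 0.2, 0.002)
        plane = np.array([[x, y, 0.0] for x in xs for y in xs])
        ref = PointCloud(plane)
        cmp_ = PointCloud(plane[::7] + [0, 0, 0.004])
        dev = chamfer_deviation(cmp_, ref)
        assert abs(dev.distances.mean() - 0.004) < 2e-4

    def test_equals_brute_force_exactly(self):
        rng = np.random.default_rng(12)
        a = PointCloud(rng.uniform(0, 1, (500, 3)))
        b = PointCloud(rng.uniform(0, 1, (500, 3)))
        dev = chamfer_deviation(a, b)
        brute = cdist(a.points, b.points).min(axis=1)
        assert np.array_equal(dev.distances, brute)

    def test_negative_distances_rejected(self):
        with pytest.raises(ValueError):
            DeviationMap(np.array([-0.1]), method="chamfer")


class TestQuadricDeviation:
    def test_exact_on_plane(self):
        xs = np.arange(0, 0.1, 0.004)
        ref = PointCloud(np.array([[x, y, 0.0] for x in xs for y in xs]))
        cmp_ = PointCloud(np.array([[0.05, 0.05, 0.01]]))
        dev = quadric_refined_deviation(cmp_, ref)
        assert abs(dev.distances[0] - 0.01) < 1e-9

    def test_near_zero_on_quadric_surface_members(self):
        xs = np.arange(-0.1, 0.1, 0.004)
        pts = np.array([[x, y, x * x + y * y] for x in xs for y in xs])
        ref = PointCloud(pts)
        cmp_ = PointCloud(pts[::11] + 1e-12)
        dev = quadric_refined_deviation(cmp_, ref)
        assert dev.distances.mean() < 0.004 / 10.0

    def test_cylinder_offset_beats_chamfer(self):
        a = np.radians(np.arange(0, 181, 2.0))
        z = np.arange(0, 0.1, 0.002)
        A, Z = np.meshgrid(a, z, indexing="ij")
        ref_pts = np.column_stack(
            [0.05 * np.cos(A.ravel()), 0.05 * np.sin(A.ravel()), Z.ravel()]
        )
        # compared samples sit at staggered angles and +1 mm height so no
        # reference point is their exact radial counterpart
        A2, Z2 = np.meshgrid(a[:-1] + np.radians(1.0), z + 0.001, indexing="ij")
        cmp_pts = np.column_stack(
            [0.055 * np.cos(A2.ravel()), 0.055 * np.sin(A2.ravel()), Z2.ravel()]
        )
        ref, cmp_ = PointCloud(ref_pts), PointCloud(cmp_pts[::5])
        cham = chamfer_deviation(cmp_, ref)
        quad = quadric_refined_deviation(cmp_, ref)
        err_c = np.abs(cham.distances - 0.005).mean()
        err_q = np.abs(quad.distances - 0.005).mean()
        assert err_q < err_c
        # refinement never exceeds the chamfer bound
        assert np.all(quad.distances <= cham.distances + 1e-12)

    def test_degenerate_neighborhood_falls_back(self):
        # collinear reference: rank-deficient quadric for every point
        ref = PointCloud(np.column_stack([np.arange(20) * 0.01,
                                          np.zeros(20), np.zeros(20)]))
        cmp_ = PointCloud(np.array([[0.05, 0.02, 0.0]]))
        dev = quadric_refined_deviation(cmp_, ref, neighborhood_k=8)
        assert dev.n_fallback == 1

    def test_small_k_rejected(self):
        ref = PointCloud(np.random.default_rng(0).uniform(0, 1, (30, 3)))
        with pytest.raises(ValueError):
            quadric_refined_deviation(ref, ref, neighborhood_k=5)


class TestDeviationSummary:
    def test_hand_built_arithmetic(self):
        dev = DeviationMap(np.array([0.01, 0.03, 0.08]), method="chamfer")
        s = deviation_summary(dev)
        assert np.isclose(s["mean"], 0.04) and np.isclose(s["max"], 0.08)

    def test_all_zero(self):
        s = deviation_summary(DeviationMap(np.zeros(5), method="chamfer"))
        assert s["mean"] == 0.0 and s["max"] == 0.0

    def test_per_label_statistics_localize_movement(self):
        d = np.concatenate([np.full(50, 0.001), np.full(30, 0.05)])
        labels = np.concatenate([np.full(50, 1), np.full(30, 2)])
        s = deviation_summary(DeviationMap(d, method="chamfer"), labels)
        assert np.isclose(s["per_label"][2]["mean"], 0.05)
        assert s["max"] == s["per_label"][2]["max"]

    def test_label_length_mismatch(self):
        with pytest.raises(ValueError):
            deviation_summary(
                DeviationMap(np.zeros(4), method="chamfer"), np.zeros(3)
            )
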