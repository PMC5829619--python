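"""Symmetry completion, canopy meshing and convex-hull volumes."""

import numpy as np
import pytest

import leafmotion as lm
from leafmotion.canopy import (
    build_mesh,
    convex_hull_volume,
    symmetry_complete,
    volume_change,
)
from leafmotion.cloud import PointCloud

SPHERE_VOLUME_DM3 = 4.0 / 3.0 * np.pi * 0.1**3 * 1000.0  # r = 0.1 m


class TestConvexHullVolume:
    def test_cube_closed_form(self):
        corners = np.array(
            [[x, y, z] for x in (0, 0.1) for y in (0, 0.1) for z in (0, 0.1)]
        )
        assert abs(convex_hull_volume(corners) - 1.0) < 1e-12

    def test_regular_tetrahedron_closed_form(self):
        a = 0.1
        pts = a / (2.0 * np.sqrt(2.0)) * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1.0]]
        )
        expect = a**3 / (6.0 * np.sqrt(2.0)) * 1000.0  # 0.117851 dm3
        assert abs(convex_hull_volume(pts) - expect) < 1e-9

    def test_ball_sampling_convergence(self):
        # error vs the analytic ball volume shrinks with sample count
        rng = np.random.default_rng(13)
        r = 0.2
        expect = 4.0 / 3.0 * np.pi * r**3 * 1000.0
        errs = []
        for n in (1000, 10_000, 100_000):
            pts = rng.uniform(-r, r, (int(n * 2.2), 3))
            pts = pts[np.linalg.norm(pts, axis=1) <= r][:n]
            errs.append(abs(convex_hull_volume(pts) - expect) / expect)
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 0.02

    def test_monotone_under_point_addition(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0, 0.1, (50, 3))
        t = rng.uniform(0, 0.12, (20, 3))
        assert convex_hull_volume(np.vstack([s, t])) >= convex_hull_volume(s)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 0.1, (200, 3))
        a = np.radians(33.0)
        R = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]
        )
        v0 = convex_hull_volume(pts)
        v1 = convex_hull_volume(pts @ R.T + [1.0, -2.0, 0.5])
        assert abs(v1 - v0) / v0 < 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_volume(np.zeros((3, 3)))
        plane = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.0]])
        with pytest.raises(ValueError):
            convex_hull_volume(plane)


class TestBuildMesh:
    def test_tetrahedron_faces_and_volume(self):
        pts = np.array([[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0], [0, 0, 0.1]])
        mesh = build_mesh(PointCloud(pts), smooth_passes=0)
        assert len(mesh.faces) == 4
        expect = abs(np.linalg.det(pts[1:] - pts[0])) / 6.0
        assert abs(abs(mesh.volume) - expect) < 1e-12
        assert mesh.metadata["watertight"]

    def test_sphere_area_close_to_analytic(self, sphere_points):
        mesh = build_mesh(PointCloud(sphere_points[::8]), smooth_passes=0)
        assert abs(mesh.area - 4 * np.pi * 0.01) / (4 * np.pi * 0.01) < 0.03

    def test_smoothing_is_volume_bounded(self, sphere_points):
        pts = sphere_points[::8]
        raw = build_mesh(PointCloud(pts), smooth_passes=0)
        smoothed = build_mesh(PointCloud(pts), smooth_passes=3)
        v0 = convex_hull_volume(np.asarray(raw.vertices))
        v1 = convex_hull_volume(np.asarray(smoothed.vertices))
        assert abs(v1 - v0) / v0 < 0.02

    def test_coplanar_input_flagged(self):
        xs = np.arange(6) * 0.01
        plane = np.array([[x, y, 0.0] for x in xs for y in xs])
        with pytest.raises(ValueError):
            build_mesh(PointCloud(plane))


class TestSymmetryComplete:
    def test_symmetric_cloud_volume_unchanged(self, sphere_points):
        cloud = PointCloud(sphere_points)
        completed, _ = symmetry_complete(cloud, axis_hint=[1.0, 0, 0])
        v0 = convex_hull_volume(sphere_points)
        v1 = convex_hull_volume(completed.points)
        assert abs(v1 - v0) / v0 < 0.01

    def test_half_sphere_recovers_full_hull(self, sphere_points):
        half = sphere_points[sphere_points[:, 0] <= 0]
        completed, plane = symmetry_complete(PointCloud(half))
        v = convex_hull_volume(completed.points)
        assert abs(v - SPHERE_VOLUME_DM3) / SPHERE_VOLUME_DM3 < 0.05
        ang = np.degrees(np.arccos(min(1.0, abs(plane.normal @ [1.0, 0, 0]))))
        assert ang < 5.0

    def test_completion_never_decreases_hull(self, sphere_points):
        half = PointCloud(sphere_points[sphere_points[:, 0] <= 0])
        completed, _ = symmetry_complete(half)
        assert convex_hull_volume(completed.points) >= convex_hull_volume(
            half.points
        ) - 1e-12

    def test_mirrored_points_are_tagged(self, sphere_points):
        half = PointCloud(sphere_points[sphere_points[:, 0] <= 0])
        completed, _ = symmetry_complete(half)
        tags = completed.attrs["synthetic"]
        assert tags.min() == 0.0 and tags.max() == 1.0
        assert (tags == 0).sum() == len(half)

    def test_plant_half_scan_plane_estimate(self, scene3):
        # porous canopies carry a weaker directional signal than solid
        # shells: the no-hint estimate lands within ~10 degrees, and the
        # acquisition-metadata hint path is exact
        view = lm.simulate_single_view(
            scene3, scanner_position=[1.5, 0.0, 0.3], angular_tol_deg=0.4
        )
        c = view.clouds[0]
        cc = c.select(np.flatnonzero(c.points[:, 2] > 0.11))
        _, plane = symmetry_complete(cc)
        ang = np.degrees(np.arccos(min(1.0, abs(plane.normal @ [1.0, 0, 0]))))
        assert ang <= 10.0
        _, hinted = symmetry_complete(cc, axis_hint=[1.0, 0, 0])
        assert abs(abs(hinted.normal @ [1.0, 0, 0]) - 1.0) < 1e-12

    def test_degenerate_spread_needs_hint(self):
        line = np.column_stack([np.zeros(30), np.zeros(30), np.arange(30.0)])
        with pytest.raises(ValueError, match="hint"):
            symmetry_complete(PointCloud(line))


class TestVolumeChange:
    def test_constant_volumes(self):
        assert volume_change([30.0, 30.0, 30.0]) == [0.0, 0.0]

    def test_printed_morning_afternoon_deltas(self):
        deltas = volume_change([33.12, 28.70, 31.27])
        assert abs(deltas[0] - (-4.42)) < 1e-9
        assert abs(deltas[1] - 2.57) < 1e-9

    def test_single_epoch_empty(self):
        assert volume_change([33.0]) == []

    def test_closing_leaves_shrink_first_interval(self):
        # fold every blade 30 degrees up toward the stem (normal elevation
        # drops 30 degrees): the canopy closes and its hull shrinks
        scene = lm.make_plant(seed=2, sampling=0.004)
        motions = [(0.0, -30.0) for _ in scene.leaf_ids()]
        lm.evolve_epoch(scene, motions)
        vols = [
            convex_hull_volume(c.points[c.points[:, 2] > 0.11])
            for c in scene.clouds
        ]
        assert volume_change(vols)[0] < 0.0
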