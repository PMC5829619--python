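"""Ground-truthed scene generator: determinism, truth closure, occlusion."""

import numpy as np
import pytest

import leafmotion as lm
from leafmotion.orientation import leaf_normal_pca, spherical_angles
from leafmotion.synthetic import (
    draw_motions,
    evolve_epoch,
    make_leaf,
    make_plant,
    simulate_single_view,
)


def angle_deg(a, b):
    return np.degrees(np.arccos(min(1.0, abs(float(np.dot(a, b))))))


class TestMakeLeaf:
    def test_planar_limit_pca_equals_analytic(self):
        pts, analytic = make_leaf(
            length=0.12, width=0.06, curvature=0.0,
            orientation=(30.0, 55.0), attachment=[0, 0, 0], sampling=0.003,
        )
        assert angle_deg(leaf_normal_pca(pts), analytic) < 1e-4
        theta, phi = spherical_angles(analytic)
        assert abs(theta - 30.0) < 1e-6 and abs(phi - 55.0) < 1e-6

    def test_curved_leaf_pca_close_to_analytic(self):
        pts, analytic = make_leaf(
            length=0.15, width=0.08, curvature=1.0,
            orientation=(-60.0, 45.0), attachment=[0.05, 0, 0.2], sampling=0.003,
        )
        assert angle_deg(leaf_normal_pca(pts), analytic) < 5.0

    def test_same_seed_is_identical(self):
        kwargs = dict(length=0.1, width=0.05, curvature=0.5,
                      orientation=(0.0, 60.0), attachment=[0, 0, 0],
                      sampling=0.004, seed=42)
        a, _ = make_leaf(**kwargs)
        b, _ = make_leaf(**kwargs)
        assert np.array_equal(a, b)

    def test_sampling_precondition(self):
        with pytest.raises(ValueError, match="sampling"):
            make_leaf(0.1, 0.05, 0.0, (0, 45.0), [0, 0, 0], sampling=0.02)

    def test_invalid_elevation_rejected(self):
        with pytest.raises(ValueError):
            make_leaf(0.1, 0.05, 0.0, (0, 120.0), [0, 0, 0], sampling=0.004)


class TestMakePlant:
    def test_no_leaves_means_no_leaf_segments(self):
        scene = make_plant(n_leaves=0, sampling=0.004, seed=0)
        assert scene.n_leaves == 0
        assert set(np.unique(scene.labels[0])) <= {0, -1}
        cloud = scene.clouds[0]
        canopy = cloud.select(np.flatnonzero(cloud.points[:, 2] > 0.11))
        segs = lm.segment_cloud(canopy) if len(canopy) > 20 else []
        assert len(segs) == 0

    def test_every_point_labeled(self):
        scene = make_plant(seed=3, sampling=0.004)
        labels = scene.labels[0]
        assert len(labels) == len(scene.clouds[0])
        assert set(np.unique(labels)) == set(range(scene.n_leaves + 1)) | {-1}

    def test_determinism_across_runs(self):
        a = make_plant(seed=11, sampling=0.004)
        b = make_plant(seed=11, sampling=0.004)
        assert np.array_equal(a.clouds[0].points, b.clouds[0].points)
        assert np.array_equal(a.labels[0], b.labels[0])

    def test_distinct_azimuth_separation(self):
        scene = make_plant(seed=5, sampling=0.004)
        az = np.sort(
            [
                np.degrees(np.arctan2(a[1], a[0])) % 360.0
                for a in scene.attachments.values()
            ]
        )
        gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
        assert gaps.min() >= 360.0 / (2 * scene.n_leaves) - 1e-6

    def test_leaves_never_interpenetrate(self):
        from scipy.spatial import cKDTree

        scene = make_plant(seed=4, sampling=0.004)
        parts = scene.clean_parts[0]
        ids = scene.leaf_ids()
        for i, a in enumerate(ids):
            tree = cKDTree(parts[a])
            for b in ids[i + 1:]:
                assert tree.query(parts[b])[0].min() >= 0.014


class TestEvolveEpoch:
    def test_static_plant_deviation_is_noise_level(self):
        scene = make_plant(seed=7, sampling=0.004, outlier_frac=0.0)
        evolve_epoch(scene, [None] * scene.n_leaves)
        dev = lm.chamfer_deviation(scene.clouds[1], scene.clouds[0])
        # two independent 2 mm-noise drawings of the same surface
        assert dev.distances.mean() < 4 * scene.params["noise_sd"]

    def test_single_tilted_leaf_localizes_displacement(self):
        scene = make_plant(seed=8, sampling=0.004, outlier_frac=0.0)
        motions = [None] * scene.n_leaves
        motions[2] = (0.0, -35.0)
        evolve_epoch(scene, motions)
        dev = lm.chamfer_deviation(scene.clouds[1], scene.clouds[0])
        summary = lm.deviation_summary(dev, scene.labels[1])
        moved = summary["per_label"][3]
        static = [
            v["mean"] for k, v in summary["per_label"].items() if k not in (3, -1)
        ]
        assert moved["mean"] > 5 * max(static)
        assert summary["max"] == moved["max"]

    def test_truth_normal_chaining(self):
        scene = make_plant(seed=9, sampling=0.004)
        rng = np.random.default_rng(0)
        for _ in range(2):
            evolve_epoch(scene, draw_motions(scene, rng))
        for lid in scene.leaf_ids():
            n = scene.true_normals[0][lid]
            for interval in scene.true_motions:
                n = interval[lid].rotation @ n
            assert np.allclose(n, scene.true_normals[-1][lid], atol=1e-9)

    def test_wrong_motion_count_rejected(self):
        scene = make_plant(seed=1, sampling=0.004)
        with pytest.raises(ValueError):
            evolve_epoch(scene, [None] * (scene.n_leaves - 1))


class TestSingleView:
    def test_lone_facing_surface_fully_retained(self):
        # a single blade facing the scanner has no occluders; every sample
        # survives hidden-point removal
        pts, _ = make_leaf(0.1, 0.06, 0.0, (0.0, 5.0), [0, 0, 0.2],
                           sampling=0.004)
        scene = make_plant(n_leaves=0, sampling=0.004, seed=0)
        from leafmotion.cloud import PointCloud

        scene.clouds[0] = PointCloud(pts, epoch="07:00")
        scene.labels[0] = np.ones(len(pts), dtype=np.int64)
        view = simulate_single_view(scene, [2.0, 0, 0.25])
        assert len(view.clouds[0]) == len(pts)

    def test_sphere_keeps_facing_hemisphere(self, sphere_points):
        from leafmotion.cloud import PointCloud

        scene = make_plant(n_leaves=0, sampling=0.004, seed=0)
        scene.clouds[0] = PointCloud(sphere_points + [0, 0, 0.5])
        scene.labels[0] = np.zeros(len(sphere_points), dtype=np.int64)
        scanner = np.array([2.0, 0.0, 0.5])
        view = simulate_single_view(scene, scanner, angular_tol_deg=0.5)
        kept = view.clouds[0].points - [0, 0, 0.5]
        # every retained point faces the scanner (x > -r/10 hemisphere test)
        toward = (scanner - (kept + [0, 0, 0.5])) / np.linalg.norm(
            scanner - (kept + [0, 0, 0.5]), axis=1, keepdims=True
        )
        radial = kept / np.linalg.norm(kept, axis=1, keepdims=True)
        assert np.mean(np.einsum("ij,ij->i", radial, toward) > 0) > 0.97

    def test_back_leaf_occluded_by_front_leaf(self):
        # two coaxial blades; exhaustive ray check on the survivors
        front, _ = make_leaf(0.1, 0.06, 0.0, (0.0, 89.0), [0, 0, 0.3],
                             sampling=0.004)
        back = front + [0.0, 0.0, -0.15]
        from leafmotion.cloud import PointCloud

        scene = make_plant(n_leaves=0, sampling=0.004, seed=0)
        pts = np.vstack([front, back])
        scene.clouds[0] = PointCloud(pts)
        scene.labels[0] = np.concatenate(
            [np.ones(len(front)), np.full(len(back), 2)]
        ).astype(np.int64)
        scanner = np.array([0.0, 0.05, 2.0])  # looking down the axis
        view = simulate_single_view(scene, scanner, angular_tol_deg=0.5)
        labels = view.labels[0]
        # the front blade survives almost whole, the back one loses points
        assert (labels == 1).sum() > 0.95 * len(front)
        assert (labels == 2).sum() < 0.5 * len(back)

    def test_scanner_inside_canopy_rejected(self):
        scene = make_plant(seed=1, sampling=0.004)
        with pytest.raises(ValueError):
            simulate_single_view(scene, [0.0, 0.0, 0.2])
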