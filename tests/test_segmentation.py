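"""Normal estimation, octree split-and-merge and cross-epoch leaf matching."""

import numpy as np
import pytest

import leafmotion as lm
from leafmotion.cloud import PointCloud
from leafmotion.segmentation import (
    estimate_normals,
    evaluate_segmentation,
    grow_segments,
    labels_from_segments,
    ls3d_rigid_match,
    match_leaves,
    octree_split,
    segment_cloud,
)
from tests.conftest import canopy_view


def rot_about(axis, deg):
    axis = np.asarray(axis) / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def grid_patch(n=30, spacing=0.004, frame=np.eye(3), origin=(0, 0, 0)):
    xs = np.arange(n) * spacing
    pts = np.array([[x, y, 0.0] for x in xs for y in xs])
    return pts @ np.asarray(frame).T + np.asarray(origin, dtype=float)


class TestEstimateNormals:
    def test_planar_cloud_gives_vertical_normals(self):
        cloud = PointCloud(grid_patch())
        nf = estimate_normals(cloud)
        assert nf.valid.all()
        assert np.allclose(nf.normals, [0.0, 0.0, 1.0], atol=1e-9)

    def test_sphere_normals_are_radial(self, sphere_points):
        pts = sphere_points[::4]
        nf = estimate_normals(PointCloud(pts), k=12, smooth_iters=0)
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(np.abs(
            np.einsum("ij,ij->i", nf.normals, radial)), 0, 1)))
        assert np.mean(ang <= 5.0) >= 0.99

    def test_rotation_equivariance(self):
        pts = grid_patch(n=15)
        R = rot_about([1, 2, 3], 35.0)
        n0 = estimate_normals(PointCloud(pts), smooth_iters=0).normals
        n1 = estimate_normals(PointCloud(pts @ R.T), smooth_iters=0).normals
        # normals are axial: compare up to sign
        dots = np.abs(np.einsum("ij,ij->i", n0 @ R.T, n1))
        assert np.allclose(dots, 1.0, atol=1e-6)

    def test_delaunay_mode_on_plane(self):
        cloud = PointCloud(grid_patch(n=12))
        nf = estimate_normals(cloud, method="delaunay", k=8, smooth_iters=0)
        assert np.allclose(np.abs(nf.normals[nf.valid] @ [0, 0, 1.0]), 1.0,
                           atol=1e-6)

    def test_parameter_validation(self):
        cloud = PointCloud(grid_patch(n=4))
        with pytest.raises(ValueError):
            estimate_normals(cloud, method="nope")
        with pytest.raises(ValueError):
            estimate_normals(cloud, k=2)


class TestOctreeSplit:
    def test_homogeneous_patch_single_cell(self):
        # a flat patch inside one voxel terminates at depth 0
        cloud = PointCloud(grid_patch(n=5, spacing=0.003))
        nf = estimate_normals(cloud, k=8, smooth_iters=0)
        cells = octree_split(cloud, nf)
        assert len(cells) == 1 and cells[0].depth == 0
        assert cells[0].normal_spread <= 1e-6

    def test_two_orthogonal_patches_split_to_pure_cells(self):
        a = grid_patch(n=25, spacing=0.004)
        b = grid_patch(n=25, spacing=0.004,
                       frame=rot_about([1, 0, 0], 90.0), origin=(0, 0.11, 0.05))
        cloud = PointCloud(np.vstack([a, b]))
        nf = estimate_normals(cloud, k=8, smooth_iters=0)
        cells = octree_split(cloud, nf)
        assert len(cells) > 1
        # membership: every point in exactly one final cell
        seen = np.concatenate([c.point_indices for c in cells])
        assert np.array_equal(np.sort(seen), np.arange(len(cloud)))
        # cells holding only one patch are orientation-pure
        for c in cells:
            members = c.point_indices
            pure_a = members.max() < len(a)
            pure_b = members.min() >= len(a)
            if pure_a or pure_b:
                assert c.normal_spread <= 5.0

    def test_min_voxel_respected(self):
        rng = np.random.default_rng(0)
        cloud = PointCloud(rng.uniform(0, 0.2, (2000, 3)))
        nf = estimate_normals(cloud, k=8, smooth_iters=0)
        cells = octree_split(cloud, nf, min_voxel=0.018, max_iter=8)
        sizes = [float(c.bounds.max_corner[0] - c.bounds.min_corner[0])
                 for c in cells]
        assert min(sizes) >= 0.018 - 1e-12


class TestGrowSegments:
    def test_single_patch_single_segment(self):
        cloud = PointCloud(grid_patch(n=40, spacing=0.004))
        segs = segment_cloud(cloud, normal_k=8)
        assert len(segs) == 1
        assert len(segs[0]) == len(cloud)

    def test_two_separated_patches_two_segments(self):
        a = grid_patch(n=30, spacing=0.004)
        b = a + [0.0, 0.0, 0.08]  # parallel, far beyond contact range
        cloud = PointCloud(np.vstack([a, b]))
        segs = segment_cloud(cloud, normal_k=8)
        assert len(segs) == 2
        got = {frozenset(s.point_indices.tolist()) for s in segs}
        want = {frozenset(range(len(a))), frozenset(range(len(a), 2 * len(a)))}
        assert got == want

    def test_partition_invariant_to_point_order(self):
        a = grid_patch(n=20, spacing=0.004)
        b = grid_patch(n=20, spacing=0.004,
                       frame=rot_about([0, 1, 0], 50.0), origin=(0.13, 0, 0.0))
        pts = np.vstack([a, b])
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(pts))
        seg1 = segment_cloud(PointCloud(pts), normal_k=8)
        seg2 = segment_cloud(PointCloud(pts[perm]), normal_k=8)
        part1 = {frozenset(s.point_indices.tolist()) for s in seg1}
        part2 = {frozenset(perm[s.point_indices].tolist()) for s in seg2}
        assert part1 == part2

    def test_requires_points_argument(self):
        with pytest.raises(ValueError):
            grow_segments([])


class TestNineLeafScene:
    def test_nine_segments_recovered(self, scene3, segmented3):
        cloud, ref, segs = segmented3[0]
        assert len(segs) == scene3.n_leaves
        labels = labels_from_segments(segs, len(cloud))
        _, acc = evaluate_segmentation(labels, ref)
        assert acc >= 95.0

    def test_segments_are_disjoint_and_sorted(self, segmented3):
        _, _, segs = segmented3[0]
        all_idx = np.concatenate([s.point_indices for s in segs])
        assert len(all_idx) == len(set(all_idx.tolist()))
        sizes = [len(s) for s in segs]
        assert sizes == sorted(sizes, reverse=True)
        assert [s.leaf_id for s in segs] == list(range(1, len(segs) + 1))


class TestLS3DMatch:
    def test_identity_surfaces(self):
        pts = grid_patch(n=20, spacing=0.004)
        t, rms, _ = ls3d_rigid_match(pts, pts)
        assert rms < 1e-9
        assert t.rotation_angle_deg() < 1e-6

    def test_recovers_known_rigid_motion(self):
        rng = np.random.default_rng(8)
        pts = grid_patch(n=25, spacing=0.004)
        pts = pts + np.column_stack(
            [np.zeros(len(pts)), np.zeros(len(pts)),
             0.5 * (pts[:, 0] ** 2 + pts[:, 1] ** 2)]
        )  # curved patch: well-constrained in all six parameters
        R = rot_about([0.2, 1, 0.1], 12.0)
        t_vec = [0.02, -0.01, 0.03]
        moved = pts @ R.T + t_vec
        t, rms, _ = ls3d_rigid_match(moved, pts)
        assert rms < 1e-6
        back = t.apply(moved)
        assert np.abs(back - pts).max() < 1e-5

    def test_match_identity_segment_sets(self, segmented3):
        import copy

        _, _, segs = segmented3[0]
        later = copy.deepcopy(segs)
        for s in later:
            s.epoch = "12:30"
        tracks = match_leaves(segs, later)
        paired = [t for t in tracks if len(t.segments) == 2]
        # identical geometry: every leaf matches itself at zero residual
        assert len(paired) == len(segs)
        for t in paired:
            assert t.segments["07:00"].leaf_id == t.segments["12:30"].leaf_id
            assert all(r < 1e-6 for r in t.residuals.values())

    def test_cross_epoch_correspondence_is_exact(self, scene3, segmented3):
        (c0, r0, s0), (c1, r1, s1) = segmented3[0], segmented3[1]
        tracks = match_leaves(s0, s1)
        paired = [t for t in tracks if len(t.segments) == 2]
        assert len(paired) == scene3.n_leaves
        for t in paired:
            majors = []
            for (seg, ref) in zip(t.segments.values(), (r0, r1)):
                labs = ref[seg.point_indices]
                majors.append(int(np.bincount(labs[labs >= 0]).argmax()))
            assert majors[0] == majors[1] > 0


class TestEvaluate:
    def test_identical_labelings(self):
        labels = np.array([1, 1, 2, 2, 0, 3])
        cm, acc = evaluate_segmentation(labels, labels)
        assert acc == 100.0
        off_diag = cm.to_numpy() - np.diag(np.diag(cm.to_numpy()))
        assert off_diag.sum() == 0

    def test_hand_counted_swap(self):
        ref = np.array([1] * 5 + [2] * 5)
        auto = ref.copy()
        auto[4], auto[9] = 2, 1  # one point of each class swapped
        cm, acc = evaluate_segmentation(auto, ref)
        assert acc == 80.0
        assert cm.loc[1, 2] == 1 and cm.loc[2, 1] == 1

    def test_hungarian_assignment_option(self):
        ref = np.array([1] * 6 + [2] * 6)
        auto = np.array([5] * 6 + [9] * 6)  # renamed classes
        _, acc = evaluate_segmentation(auto, ref, assignment="hungarian")
        assert acc == 100.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_segmentation(np.zeros(3), np.zeros(4))
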