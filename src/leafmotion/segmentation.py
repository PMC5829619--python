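"""Individual-leaf extraction by octree split-and-merge on point normals,
and leaf correspondence across epochs by least-squares surface matching.

The segmentation exploits the fact that a rosette plant's leaves present
locally homogeneous surface orientation while stems, pot rims and leaf
edges do not:

1.  per-point unit normals are estimated (local-Delaunay facet averaging or
    plane fitting);
2.  the cloud is organized in an octree; a cell is subdivided while the
    angular spread of its normals exceeds a tolerance, until a minimum
    voxel size or maximum depth is reached;
3.  cells whose normals still vary strongly (leaf edges, stem) are removed;
4.  remaining cells are merged bottom-up: the flattest unassigned cell
    seeds a segment that grows over face-adjacent cells while orientation
    homogeneity is maintained.

Normal spread is measured as the mean angular deviation (degrees) from the
cell's mean normal.  All normal statistics are axial (sign-invariant): a
normal is an axis, not an arrow, and a blade standing on edge must not
appear to carry two opposite normal populations.

Segments from different acquisition times are matched pairwise by a rigid
least-squares 3D surface match (point-to-plane Gauss–Markov iteration):
a candidate pair is accepted when its RMS surface residual is below a
threshold, and accepted pairs are assigned one-to-one by centroid
proximity with the residual as tie-breaker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .cloud import BoundingBox, PointCloud
from .registration import RigidTransform

__all__ = [
    "NormalField",
    "OctreeCell",
    "LeafSegment",
    "LeafTrack",
    "estimate_normals",
    "octree_split",
    "grow_segments",
    "segment_cloud",
    "labels_from_segments",
    "match_leaves",
    "evaluate_segmentation",
]

# paper-anchored defaults
MIN_VOXEL = 0.018        # m, minimum octree cell size
MAX_DEPTH = 5            # octree subdivision iterations
SPREAD_TOL = 15.0        # deg, cell homogeneity tolerance
MERGE_TOL = 20.0         # deg, segment-growth homogeneity tolerance
LSM_THRESHOLD = 0.038    # m, LS3D surface-match acceptance threshold
MIN_POINTS = 50          # smallest admissible leaf segment


# ---------------------------------------------------------------------------
# normals


@dataclass
class NormalField:
    """Per-point unit normals with validity flags."""

    normals: np.ndarray
    valid: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.normals = np.asarray(self.normals, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)


def canonicalize_signs(normals: np.ndarray) -> np.ndarray:
    """Flip normals into the +z hemisphere (ties toward +x, then +y).

    Facet and covariance normals carry an arbitrary sign; a consistent
    hemisphere makes angular-spread statistics meaningful.
    """
    n = np.array(normals, dtype=np.float64)
    key = n[:, 2].copy()
    tie = np.abs(key) < 1e-12
    key[tie] = n[tie, 0]
    tie2 = tie & (np.abs(n[:, 0]) < 1e-12)
    key[tie2] = n[tie2, 1]
    n[key < 0] *= -1.0
    return n


def _plane_fit_normals(pts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    tree = cKDTree(pts)
    k_eff = min(k + 1, len(pts))
    _, idx = tree.query(pts, k=k_eff)
    nbrs = pts[idx]  # (N, k+1, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    normals = vecs[:, :, 0]
    # degenerate: collinear neighborhood (two smallest eigenvalues ~ 0)
    scale = np.maximum(vals[:, 2], 1e-300)
    valid = (vals[:, 1] / scale) > 1e-8
    return normals, valid


def _delaunay_normals(pts: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Average area-weighted normals of local tangent-plane Delaunay facets
    incident to each query point."""
    plane_n, valid = _plane_fit_normals(pts, k)
    tree = cKDTree(pts)
    k_eff = min(k + 1, len(pts))
    _, idx = tree.query(pts, k=k_eff)
    normals = np.zeros_like(pts)
    for i in range(len(pts)):
        if not valid[i]:
            continue
        nbrs = pts[idx[i]] - pts[i]
        nrm = plane_n[i]
        # local tangent basis
        a = np.array([1.0, 0.0, 0.0])
        if abs(nrm[0]) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(nrm, a)
        u /= np.linalg.norm(u)
        v = np.cross(nrm, u)
        uv = np.column_stack([nbrs @ u, nbrs @ v])
        try:
            tri = Delaunay(uv, qhull_options="QJ")
        except Exception:
            normals[i] = nrm
            continue
        acc = np.zeros(3)
        for simplex in tri.simplices:
            if 0 not in simplex:  # index 0 is the query point itself
                continue
            p0, p1, p2 = nbrs[simplex]
            fn = np.cross(p1 - p0, p2 - p0)  # 2x facet area times unit normal
            if fn @ nrm < 0:
                fn = -fn
            acc += fn
        norm = np.linalg.norm(acc)
        normals[i] = acc / norm if norm > 0 else nrm
    return normals, valid


def estimate_normals(
    cloud: PointCloud,
    method: str = "plane_fit",
    k: int = 20,
    smooth_iters: int = 1,
) -> NormalField:
    """Estimate a unit normal per point.

    ``plane_fit`` (default, robust) takes the smallest-eigenvector of the
    k-neighborhood covariance; ``delaunay`` triangulates each neighborhood
    in its tangent plane and averages incident facet normals.  Signs are
    canonicalized into the +z hemisphere.  Degenerate (collinear)
    neighborhoods are flagged invalid and excluded from segmentation.

    ``smooth_iters`` passes of sign-aligned neighborhood averaging damp the
    millimeter range noise of real scans, which otherwise dominates the
    normal of a neighborhood only a few point-spacings wide; smoothing is
    what makes the octree homogeneity statistics reflect surface
    orientation rather than sensor noise.
    """
    if method not in ("plane_fit", "delaunay"):
        raise ValueError(f"unknown normal method {method!r}")
    if k < 3:
        raise ValueError("k must be >= 3")
    if len(cloud) < 4:
        raise ValueError("need at least 4 points to estimate normals")
    pts = cloud.points
    if method == "plane_fit":
        normals, valid = _plane_fit_normals(pts, k)
    else:
        normals, valid = _delaunay_normals(pts, k)
    lens = np.linalg.norm(normals, axis=1)
    bad = lens < 1e-12
    valid = valid & ~bad
    lens[bad] = 1.0
    normals = normals / lens[:, None]
    if smooth_iters > 0:
        k_eff = min(k + 1, len(pts))
        _, idx = cKDTree(pts).query(pts, k=k_eff)
        for _ in range(smooth_iters):
            nb = normals[idx]  # (N, k+1, 3)
            # align each neighbor's sign to the center normal before the mean
            sign = np.sign(np.einsum("nkj,nj->nk", nb, normals))
            sign[sign == 0] = 1.0
            avg = (nb * sign[:, :, None]).sum(axis=1)
            ln = np.linalg.norm(avg, axis=1)
            ok = ln > 1e-12
            normals[ok] = avg[ok] / ln[ok, None]
    normals = canonicalize_signs(normals)
    normals[~valid] = 0.0
    return NormalField(normals, valid, method)


# ---------------------------------------------------------------------------
# octree split


@dataclass
class OctreeCell:
    """A final octree cell: bounds, depth, member points, normal statistics."""

    bounds: BoundingBox
    depth: int
    point_indices: np.ndarray
    normal_mean: np.ndarray
    normal_spread: float  # mean angular deviation, degrees
    index: int = -1


def _normal_stats(normals: np.ndarray) -> tuple[np.ndarray, float]:
    """Axial mean direction and mean angular deviation (degrees).

    Normals are axes, not arrows (their sign is a convention), so the mean
    is the leading eigenvector of the orientation tensor Σ nᵢnᵢᵀ and all
    angles use |n·mean| — a blade standing vertically must not appear to
    carry two opposite normal populations.
    """
    if len(normals) == 0:
        return np.array([0.0, 0.0, 1.0]), 90.0
    T = normals.T @ normals
    _, vecs = np.linalg.eigh(T)
    mean = vecs[:, -1]
    mean = canonicalize_signs(mean[None])[0]
    ang = np.degrees(np.arccos(np.clip(np.abs(normals @ mean), 0.0, 1.0)))
    return mean, float(ang.mean())


def _axial_angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two axes (sign-invariant), degrees, in [0, 90]."""
    return float(np.degrees(np.arccos(np.clip(abs(float(a @ b)), 0.0, 1.0))))


def octree_split(
    cloud: PointCloud,
    normals: NormalField,
    min_voxel: float = MIN_VOXEL,
    spread_tol: float = SPREAD_TOL,
    max_iter: int = MAX_DEPTH,
) -> list[OctreeCell]:
    """Recursive 8-way subdivision driven by normal homogeneity.

    The root cell is the cubic bounding box of the cloud.  A cell is final
    when its normals' angular spread is within ``spread_tol``, when halving
    it would produce cells smaller than ``min_voxel``, or when ``max_iter``
    subdivision levels are reached.  Points with invalid normals are left
    out; every remaining point ends up in exactly one final cell.
    """
    if min_voxel <= 0:
        raise ValueError("min_voxel must be positive")
    pts = cloud.points
    alive = np.flatnonzero(normals.valid)
    box = cloud.bounding_box()
    size = float((box.max_corner - box.min_corner).max())
    size = max(size, min_voxel)
    center = (box.min_corner + box.max_corner) / 2.0
    root_lo = center - size / 2.0

    final: list[OctreeCell] = []

    def visit(idx: np.ndarray, lo: np.ndarray, size: float, depth: int) -> None:
        if idx.size == 0:
            return
        mean, spread = _normal_stats(normals.normals[idx])
        if spread <= spread_tol or depth >= max_iter or size / 2.0 < min_voxel:
            final.append(
                OctreeCell(
                    bounds=BoundingBox(lo, lo + size),
                    depth=depth,
                    point_indices=idx,
                    normal_mean=mean,
                    normal_spread=spread,
                )
            )
            return
        half = size / 2.0
        mid = lo + half
        octant = (
            (pts[idx, 0] >= mid[0]).astype(np.int8)
            + 2 * (pts[idx, 1] >= mid[1]).astype(np.int8)
            + 4 * (pts[idx, 2] >= mid[2]).astype(np.int8)
        )
        for o in range(8):
            sub = idx[octant == o]
            off = lo + half * np.array([o & 1, (o >> 1) & 1, (o >> 2) & 1])
            visit(sub, off, half, depth + 1)

    visit(alive, root_lo, size, 0)
    for i, cell in enumerate(final):
        cell.index = i
    return final


# ---------------------------------------------------------------------------
# bottom-up merge


@dataclass
class LeafSegment:
    """One leaf at one epoch."""

    leaf_id: int
    epoch: str
    point_indices: np.ndarray
    points: np.ndarray
    centroid: np.ndarray
    pca_normal: np.ndarray
    flatness: float  # smallest/middle covariance eigenvalue ratio (0 = flat)
    cell_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.point_indices)


def _segment_pca(points: np.ndarray) -> tuple[np.ndarray, float]:
    c = points - points.mean(axis=0)
    vals, vecs = np.linalg.eigh(c.T @ c / max(len(points), 1))
    n = canonicalize_signs(vecs[:, 0][None])[0]
    flat = float(vals[0] / vals[1]) if vals[1] > 0 else 0.0
    return n, flat


def _in_contact(pts_a: np.ndarray, pts_b: np.ndarray, gap: float) -> bool:
    """True when two point sets share a genuine surface contact.

    Requires several close pairs (3, or 2% of the smaller set): with
    millimeter range noise a single extreme pair can fall under ``gap``
    across a real inter-leaf gap, and one noisy point must not bridge two
    separate surfaces.
    """
    need = max(3, int(0.02 * min(len(pts_a), len(pts_b))))
    d = cKDTree(pts_b).query(pts_a, distance_upper_bound=gap)[0]
    return int(np.isfinite(d).sum()) >= need


def _face_adjacent(a: BoundingBox, b: BoundingBox, tol: float = 1e-9) -> bool:
    """Axis-aligned boxes sharing (part of) a face, any depths."""
    touch_axis = -1
    for ax in range(3):
        lo = max(a.min_corner[ax], b.min_corner[ax])
        hi = min(a.max_corner[ax], b.max_corner[ax])
        if hi - lo < -tol:
            return False
        if hi - lo <= tol:  # touching, not overlapping, on this axis
            if touch_axis >= 0:
                return False  # edge or corner contact only
            touch_axis = ax
    return touch_axis >= 0


def _split_cell_components(
    cells: list[OctreeCell],
    points: np.ndarray,
    gap: float,
    normals: NormalField | None = None,
) -> list[OctreeCell]:
    """Split each cell into single-linkage components at distance ``gap``.

    A cell holding two stacked leaf sheets becomes two spatially coherent
    components instead of one mixed (and falsely bridging) cell; each
    component gets its own normal statistics when ``normals`` is given.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    out: list[OctreeCell] = []
    for cell in cells:
        idx = cell.point_indices
        if len(idx) <= 1:
            out.append(cell)
            continue
        sub = points[idx]
        pairs = cKDTree(sub).query_pairs(gap, output_type="ndarray")
        if len(pairs) == 0:
            n_comp, comp = len(idx), np.arange(len(idx))
        else:
            graph = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                shape=(len(idx), len(idx)),
            )
            n_comp, comp = connected_components(graph, directed=False)
        if n_comp == 1:
            out.append(cell)
            continue
        for ci in range(n_comp):
            sel = idx[comp == ci]
            if normals is not None:
                mean, spread = _normal_stats(normals.normals[sel])
            else:
                mean, spread = cell.normal_mean, cell.normal_spread
            out.append(
                OctreeCell(
                    bounds=cell.bounds,
                    depth=cell.depth,
                    point_indices=sel,
                    normal_mean=mean,
                    normal_spread=spread,
                    index=cell.index,
                )
            )
    for i, cell in enumerate(out):
        cell.index = i
    return out


def grow_segments(
    cells: list[OctreeCell],
    spread_tol: float = SPREAD_TOL,
    merge_tol: float = MERGE_TOL,
    min_points: int = MIN_POINTS,
    removal_tol: float | None = None,
    epoch: str = "",
    points: np.ndarray | None = None,
    assign_radius: float | None = 0.01,
    contact_gap: float = 0.01,
    normals: NormalField | None = None,
    min_width: float = 0.008,
    max_flatness: float = 0.3,
) -> list[LeafSegment]:
    """Seeded bottom-up merge of octree cells into leaf segments.

    Cells with spread above ``removal_tol`` (default 2x ``spread_tol``) are
    discarded first — these sit on leaf edges and stems.  Then, repeatedly,
    the flattest unassigned cell (lowest spread; ties: most points, lowest
    cell index) seeds a segment, which absorbs face-adjacent unassigned
    cells whose mean normal stays within ``merge_tol`` of the growing
    segment's mean normal.  Segments below ``min_points`` are dropped to
    noise; remaining unassigned points within ``assign_radius`` of a
    segment join it (``None`` disables this final pass).  Output is sorted
    by size (largest first) and re-numbered 1..n.
    """
    if removal_tol is None:
        removal_tol = 2.0 * spread_tol
    if points is None:
        raise ValueError("grow_segments needs the coordinate array via points=")
    # a final cell can straddle two separate surfaces (e.g. leaves stacked
    # closer than the minimum voxel): decompose every cell into spatially
    # connected components at grain ``contact_gap`` so no cell glues
    # distinct sheets together
    cells = _split_cell_components(cells, points, contact_gap, normals)
    survivors = [c for c in cells if c.normal_spread <= removal_tol]
    if not survivors:
        warnings.warn("no octree cells survive normal-variation removal")
        return []
    # adjacency = touching cell boxes AND actual point-set contact: two
    # distinct leaves can occupy face-adjacent cells while their surfaces
    # stay clearly separated in space
    adj: dict[int, list[int]] = {i: [] for i in range(len(survivors))}
    for i in range(len(survivors)):
        for j in range(i + 1, len(survivors)):
            if not _face_adjacent(survivors[i].bounds, survivors[j].bounds):
                continue
            if _in_contact(
                points[survivors[i].point_indices],
                points[survivors[j].point_indices],
                contact_gap,
            ):
                adj[i].append(j)
                adj[j].append(i)

    order = sorted(
        range(len(survivors)),
        key=lambda i: (
            survivors[i].normal_spread,
            -len(survivors[i].point_indices),
            survivors[i].index,
        ),
    )
    assigned = np.full(len(survivors), -1)
    groups: list[list[int]] = []
    for seed in order:
        if assigned[seed] >= 0:
            continue
        gid = len(groups)
        members = [seed]
        assigned[seed] = gid
        seed_normal = survivors[seed].normal_mean
        # running axial mean: orientation tensor weighted by cell size
        w0 = len(survivors[seed].point_indices)
        acc = w0 * np.outer(seed_normal, seed_normal)
        frontier = sorted(adj[seed])
        while frontier:
            nxt = []
            mean = np.linalg.eigh(acc)[1][:, -1]
            progressed = False
            for cand in frontier:
                if assigned[cand] >= 0:
                    continue
                cn = survivors[cand].normal_mean
                # homogeneity is anchored to both the running mean and the
                # seed normal: the former admits gentle curvature, the
                # latter stops the mean drifting across a fold onto the
                # next leaf
                ang = _axial_angle_deg(cn, mean)
                ang_seed = _axial_angle_deg(cn, seed_normal)
                if ang <= merge_tol and ang_seed <= 1.5 * merge_tol:
                    assigned[cand] = gid
                    members.append(cand)
                    w = len(survivors[cand].point_indices)
                    acc = acc + w * np.outer(cn, cn)
                    progressed = True
                    nxt.extend(adj[cand])
                else:
                    nxt.append(cand)
            if not progressed:
                break
            frontier = sorted(set(n for n in nxt if assigned[n] < 0))
        groups.append(members)

    # segment-level re-merge: growth can sever one leaf at a removed edge
    # band; two groups that are in physical contact and orientation-
    # compatible are the same surface.  Distinct leaves never touch, so
    # this cannot join them.
    group_sets = [
        (
            np.concatenate([survivors[m].point_indices for m in members]),
            members,
        )
        for members in groups
    ]
    merged = True
    while merged:
        merged = False
        for a in range(len(group_sets)):
            for b in range(a + 1, len(group_sets)):
                idx_a, mem_a = group_sets[a]
                idx_b, mem_b = group_sets[b]
                na, _ = _normal_stats(
                    np.vstack([survivors[m].normal_mean for m in mem_a])
                )
                nb, _ = _normal_stats(
                    np.vstack([survivors[m].normal_mean for m in mem_b])
                )
                if _axial_angle_deg(na, nb) > merge_tol:
                    continue
                if _in_contact(points[idx_a], points[idx_b], contact_gap):
                    group_sets[a] = (np.concatenate([idx_a, idx_b]), mem_a + mem_b)
                    del group_sets[b]
                    merged = True
                    break
            if merged:
                break

    raw: list[tuple[np.ndarray, list[int]]] = []
    for idx, members in group_sets:
        if idx.size < min_points:
            continue
        raw.append((np.sort(idx), sorted(survivors[m].index for m in members)))

    # final point-level pass: edge points whose cells were removed (or whose
    # groups were too small) join the nearest segment when within reach —
    # the region's shape, not its cell decomposition, decides membership
    if assign_radius is not None and raw:
        assigned_idx = np.concatenate([idx for idx, _ in raw])
        owner = np.concatenate(
            [np.full(len(idx), g) for g, (idx, _) in enumerate(raw)]
        )
        mask = np.ones(len(points), dtype=bool)
        mask[assigned_idx] = False
        remainder = np.flatnonzero(mask)
        if remainder.size:
            dist, near = cKDTree(points[assigned_idx]).query(points[remainder])
            take = dist <= assign_radius
            extra: dict[int, list[int]] = {}
            for pt_i, o in zip(remainder[take], owner[near[take]]):
                extra.setdefault(int(o), []).append(int(pt_i))
            raw = [
                (
                    np.sort(np.concatenate([idx, np.array(extra[g], dtype=idx.dtype)]))
                    if g in extra
                    else idx,
                    cells_,
                )
                for g, (idx, cells_) in enumerate(raw)
            ]

    segments = []
    for idx, cell_idx in raw:
        seg_pts = points[idx]
        # shape gate, applied on the final point sets: a leaf blade is a
        # locally planar two-dimensional patch — wide across its second
        # principal axis and thin across the third.  Millimeter-wide
        # strips (stem sectors) and tubular chunks (whole stem pieces,
        # λ0 ≈ λ1) survive the normal-homogeneity tests but are not
        # leaves; both drop to noise here.
        c = seg_pts - seg_pts.mean(axis=0)
        vals = np.linalg.eigvalsh(c.T @ c / len(idx))
        if np.sqrt(max(vals[1], 0.0)) < min_width:
            continue
        if vals[1] > 0 and vals[0] / vals[1] > max_flatness:
            continue
        n, flat = _segment_pca(seg_pts)
        segments.append(
            LeafSegment(
                leaf_id=0,
                epoch=epoch,
                point_indices=idx,
                points=seg_pts,
                centroid=seg_pts.mean(axis=0),
                pca_normal=n,
                flatness=flat,
                cell_indices=cell_idx,
            )
        )
    segments.sort(key=lambda s: (-len(s), s.point_indices[0]))
    for i, s in enumerate(segments, start=1):
        s.leaf_id = i
    return segments


def segment_cloud(
    cloud: PointCloud,
    normal_method: str = "plane_fit",
    normal_k: int = 12,
    min_voxel: float = MIN_VOXEL,
    max_iter: int = MAX_DEPTH,
    spread_tol: float = SPREAD_TOL,
    merge_tol: float = MERGE_TOL,
    min_points: int = MIN_POINTS,
    assign_radius: float | None = 0.01,
) -> list[LeafSegment]:
    """Convenience wrapper: normals → octree split → bottom-up merge."""
    normals = estimate_normals(cloud, method=normal_method, k=normal_k)
    cells = octree_split(cloud, normals, min_voxel, spread_tol, max_iter)
    return grow_segments(
        cells,
        spread_tol=spread_tol,
        merge_tol=merge_tol,
        min_points=min_points,
        epoch=cloud.epoch,
        points=cloud.points,
        assign_radius=assign_radius,
        normals=normals,
    )


def labels_from_segments(segments: list[LeafSegment], n_points: int) -> np.ndarray:
    """Dense per-point leaf labels (0 = unassigned/noise)."""
    labels = np.zeros(n_points, dtype=np.int64)
    for seg in segments:
        labels[seg.point_indices] = seg.leaf_id
    return labels


# ---------------------------------------------------------------------------
# LS3D surface matching across epochs


@dataclass
class LeafTrack:
    """The same physical leaf matched across epochs."""

    leaf_id: int
    segments: dict[str, LeafSegment]
    transforms: dict[tuple[str, str], RigidTransform] = field(default_factory=dict)
    residuals: dict[tuple[str, str], float] = field(default_factory=dict)
    matched: dict[tuple[str, str], bool] = field(default_factory=dict)

    @property
    def epochs(self) -> list[str]:
        return list(self.segments)


def _pca_frame(points: np.ndarray) -> np.ndarray:
    """Right-handed principal frame, columns = axes (desc. eigenvalue)."""
    c = points - points.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    frame = vecs[:, ::-1]
    if np.linalg.det(frame) < 0:
        frame[:, 2] *= -1
    return frame


def _init_guesses(compared: np.ndarray, reference: np.ndarray) -> list[RigidTransform]:
    """Coarse alignment hypotheses: centroid shift, plus PCA-frame
    alignments over the four proper sign combinations of the leading axes
    (a leaf rotated by tens of degrees is far outside the basin of a
    centroid-only start)."""
    cc, rc = compared.mean(axis=0), reference.mean(axis=0)
    guesses = [RigidTransform(np.eye(3), rc - cc)]
    fa, fb = _pca_frame(compared), _pca_frame(reference)
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        fb_s = fb * np.array([s1, s2, s1 * s2])
        R = fb_s @ fa.T
        guesses.append(RigidTransform(R, rc - R @ cc))
    return guesses


def ls3d_rigid_match(
    compared: np.ndarray,
    reference: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-6,
    init: RigidTransform | None = None,
) -> tuple[RigidTransform, float, bool]:
    """Rigid least-squares 3D surface match (Gauss–Markov iteration).

    Estimates the rigid transform of the compared surface onto the
    reference surface by minimizing the squared sum of point-to-surface
    Euclidean residuals: correspondences by nearest neighbor, residuals
    projected on local reference-surface normals, 6-parameter linearized
    update solved in closed form each iteration.  Starts from ``init``
    when given, otherwise from the best of several coarse PCA-frame
    alignments.  Returns ``(transform, rms_residual, converged)``.
    """
    ref_tree = cKDTree(reference)
    k = min(11, len(reference))
    _, nbr = ref_tree.query(reference, k=k)
    nb = reference[nbr]
    cen = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", cen, cen)
    _, vecs = np.linalg.eigh(cov)
    ref_normals = vecs[:, :, 0]

    if init is not None:
        current = init
    else:
        current = min(
            _init_guesses(compared, reference),
            key=lambda t: float(ref_tree.query(t.apply(compared))[0].mean()),
        )
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        moved = current.apply(compared)
        _, idx = ref_tree.query(moved)
        q = reference[idx]
        n = ref_normals[idx]
        r = np.einsum("ij,ij->i", moved - q, n)  # signed surface residuals
        rms = float(np.sqrt(np.mean(r**2)))
        if not np.isfinite(rms):
            return current, np.inf, False
        if abs(prev - rms) < tol:
            converged = True
            break
        prev = rms
        # J row: [ (p × n), n ] for params (ω, t)
        J = np.hstack([np.cross(moved, n), n])
        JTJ = J.T @ J
        try:
            delta = np.linalg.solve(JTJ + 1e-12 * np.eye(6), -J.T @ r)
        except np.linalg.LinAlgError:
            break
        w, t = delta[:3], delta[3:]
        theta = np.linalg.norm(w)
        if theta < 1e-15:
            R = np.eye(3)
        else:
            axis = w / theta
            K = np.array(
                [
                    [0, -axis[2], axis[1]],
                    [axis[2], 0, -axis[0]],
                    [-axis[1], axis[0], 0],
                ]
            )
            R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        current = RigidTransform(R, t).compose(current)
    moved = current.apply(compared)
    _, idx = ref_tree.query(moved)
    r = np.einsum("ij,ij->i", moved - reference[idx], ref_normals[idx])
    return current, float(np.sqrt(np.mean(r**2))), converged


def match_leaves(
    segments_a: list[LeafSegment],
    segments_b: list[LeafSegment],
    lsm_threshold: float = LSM_THRESHOLD,
    centroid_cap: float = 0.15,
) -> list[LeafTrack]:
    """Match leaf segments of epoch A to epoch B by LS3D surface matching.

    Candidate pairs within ``centroid_cap`` of each other are ranked by
    centroid proximity; each is scored by the converged RMS residual of a
    rigid surface match (A onto B) and accepted when the residual is below
    ``lsm_threshold``.  Pairs are assigned one-to-one greedily by lowest
    residual; unmatched segments produce single-epoch tracks flagged
    unmatched.
    """
    candidates = []
    for sa in segments_a:
        for sb in segments_b:
            gap = float(np.linalg.norm(sa.centroid - sb.centroid))
            if gap <= centroid_cap:
                candidates.append((gap, sa, sb))
    candidates.sort(key=lambda c: c[0])
    scored = []
    for gap, sa, sb in candidates:
        transform, rms, converged = ls3d_rigid_match(sa.points, sb.points)
        # a diverged iteration surfaces as a non-finite or large residual;
        # a residual that plateaued at threshold level without meeting the
        # strict tolerance is still a valid surface match
        if np.isfinite(rms) and rms <= lsm_threshold:
            scored.append((gap, rms, sa, sb, transform))
    # assignment: centroid proximity first, residual as tie-breaker — the
    # residual gate above rejects implausible surfaces, but leaves of one
    # plant are similar enough in shape that residual alone cannot rank
    # pairings, while leaf displacement between epochs stays well below
    # the inter-leaf spacing
    scored.sort(key=lambda s: (s[0], s[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    tracks = []
    for gap, rms, sa, sb, transform in scored:
        if id(sa) in used_a or id(sb) in used_b:
            continue
        used_a.add(id(sa))
        used_b.add(id(sb))
        key = (sa.epoch, sb.epoch)
        tracks.append(
            LeafTrack(
                leaf_id=sa.leaf_id,
                segments={sa.epoch: sa, sb.epoch: sb},
                transforms={key: transform},
                residuals={key: rms},
                matched={key: True},
            )
        )
    for sa in segments_a:
        if id(sa) not in used_a:
            tracks.append(LeafTrack(leaf_id=sa.leaf_id, segments={sa.epoch: sa}))
    tracks.sort(key=lambda t: t.leaf_id)
    return tracks


def track_epochs(
    segmentations: list[list[LeafSegment]],
    lsm_threshold: float = LSM_THRESHOLD,
) -> list[LeafTrack]:
    """Chain pairwise epoch matches into whole-series leaf tracks."""
    if not segmentations:
        return []
    tracks = {
        s.leaf_id: LeafTrack(leaf_id=s.leaf_id, segments={s.epoch: s})
        for s in segmentations[0]
    }
    tail = {s.leaf_id: s for s in segmentations[0]}  # leaf_id -> latest segment
    for nxt in segmentations[1:]:
        prev_segs = list(tail.values())
        pairwise = match_leaves(prev_segs, nxt, lsm_threshold)
        seg_to_track = {id(s): lid for lid, s in tail.items()}
        new_tail = {}
        for pt in pairwise:
            if len(pt.segments) < 2:
                continue
            (ea, sa), (eb, sb) = list(pt.segments.items())
            lid = seg_to_track[id(sa)]
            tr = tracks[lid]
            tr.segments[eb] = sb
            tr.transforms.update(pt.transforms)
            tr.residuals.update(pt.residuals)
            tr.matched.update(pt.matched)
            new_tail[lid] = sb
        tail = new_tail
    return sorted(tracks.values(), key=lambda t: t.leaf_id)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_segmentation(
    auto_labels: np.ndarray,
    ref_labels: np.ndarray,
    assignment: str = "majority",
):
    """Point-wise confusion matrix and global accuracy (%).

    Automatic classes are mapped to reference classes by majority overlap
    (default) or optimally by the Hungarian algorithm on the overlap-count
    matrix.  Reference labels <= 0 (stem/pot = 0, injected outliers = -1)
    and unassigned automatic points (label 0) form a shared "noise" class.
    Global accuracy = trace / total x 100.
    """
    import pandas as pd

    auto = np.asarray(auto_labels)
    ref = np.asarray(ref_labels)
    if auto.shape != ref.shape:
        raise ValueError("label vectors differ in length")
    ref_n = np.where(ref > 0, ref, 0)
    auto_n = np.where(auto > 0, auto, 0)
    ref_classes = sorted(np.unique(ref_n))
    auto_classes = sorted(c for c in np.unique(auto_n) if c > 0)
    overlap = np.zeros((len(auto_classes), len(ref_classes)), dtype=np.int64)
    for i, a in enumerate(auto_classes):
        sel = ref_n[auto_n == a]
        for j, r in enumerate(ref_classes):
            overlap[i, j] = np.sum(sel == r)
    mapping = {0: 0}
    if assignment == "hungarian" and overlap.size:
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(-overlap)
        for i, j in zip(rows, cols):
            mapping[auto_classes[i]] = ref_classes[j]
        for a in auto_classes:
            mapping.setdefault(a, 0)
    else:
        for i, a in enumerate(auto_classes):
            mapping[a] = ref_classes[int(np.argmax(overlap[i]))] if overlap.size else 0
    mapped = np.array([mapping[a] for a in auto_n])
    classes = sorted(set(ref_classes) | set(mapping.values()))
    pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    np.add.at(
        counts,
        (
            np.array([pos[r] for r in ref_n]),
            np.array([pos[a] for a in mapped]),
        ),
        1,
    )
    cm = pd.DataFrame(
        counts,
        index=pd.Index(classes, name="reference"),
        columns=pd.Index(classes, name="auto"),
    )
    accuracy = 100.0 * np.trace(counts) / len(ref)
    return cm, float(accuracy)
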