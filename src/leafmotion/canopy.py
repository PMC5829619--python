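"""Canopy shape and whole-plant volume change.

A single-viewpoint scan sees only one side of the plant.  The poorly
visible backside is recovered by mirror symmetry: a vertical symmetry
plane is estimated (perpendicular to the viewing direction, positioned at
the occlusion rim of the visible cloud) and the visible points are
reflected across it.  The completed cloud is meshed by a Delaunay-derived
surface triangulation with a simplified repair pass (long-edge removal +
Laplacian smoothing), and the canopy's effective enveloped space is
summarized by the volume of the point set's 3D convex hull, reported in
dm³.  Volume change between acquisition times is the signed difference of
consecutive hull volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .cloud import PointCloud

__all__ = [
    "CanopyModel",
    "SymmetryPlane",
    "symmetry_complete",
    "build_mesh",
    "convex_hull_volume",
    "volume_change",
    "build_canopy_model",
]

M3_TO_DM3 = 1000.0


@dataclass(frozen=True)
class SymmetryPlane:
    """A plane given by a point on it and a unit normal (the view axis)."""

    point: np.ndarray
    normal: np.ndarray

    def mirror(self, points: np.ndarray) -> np.ndarray:
        d = (np.asarray(points) - self.point) @ self.normal
        return points - 2.0 * d[:, None] * self.normal


@dataclass
class CanopyModel:
    """Canopy of one epoch: completed points, mesh, hull and volume (dm³)."""

    completed_points: PointCloud
    mesh_vertices: np.ndarray
    mesh_faces: np.ndarray
    hull_vertices: np.ndarray
    hull_volume: float
    epoch: str = ""
    watertight: bool = False
    symmetry_plane: SymmetryPlane | None = None
    notes: dict = field(default_factory=dict)


def _horizontal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Principal axes of the horizontal (xy) spread: (major, minor, ratio)."""
    xy = points[:, :2] - points[:, :2].mean(axis=0)
    cov = xy.T @ xy / len(xy)
    vals, vecs = np.linalg.eigh(cov)  # ascending
    minor = np.array([vecs[0, 0], vecs[1, 0], 0.0])
    major = np.array([vecs[0, 1], vecs[1, 1], 0.0])
    ratio = float(np.sqrt(vals[1] / max(vals[0], 1e-300)))
    return major, minor, ratio


def _self_occlusion(
    pts: np.ndarray,
    v: np.ndarray,
    ang_tol: float = 0.6,
    depth_tol: float = 0.01,
    dist: float = 1.5,
) -> float:
    """Fraction of points hidden behind others when viewed along ``v``."""
    pos = pts.mean(axis=0) - v * dist
    d = pts - pos
    r = np.linalg.norm(d, axis=1)
    az = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    el = np.degrees(np.arcsin(np.clip(d[:, 2] / r, -1.0, 1.0)))
    key = (
        np.floor(az / ang_tol).astype(np.int64) * 10_000_000
        + np.floor(el / ang_tol).astype(np.int64)
    )
    order = np.argsort(key, kind="stable")
    ks, rs = key[order], r[order]
    occluded = 0
    start = 0
    for i in range(1, len(ks) + 1):
        if i == len(ks) or ks[i] != ks[start]:
            block = rs[start:i]
            occluded += int((block > block.min() + depth_tol).sum())
            start = i
    return occluded / len(pts)


def estimate_view_axis(
    points: np.ndarray, step_deg: float = 2.0, max_points: int = 15000
) -> np.ndarray:
    """Estimate the (axial) horizontal viewing direction of a one-sided scan.

    A cloud produced by a single-viewpoint acquisition is self-visible
    along the direction it was scanned from: re-projecting it along the
    true view axis hides almost nothing, while a sideways projection makes
    its surfaces shadow each other.  The returned horizontal unit vector
    minimizes the self-occlusion fraction over candidate azimuths; its
    sign is arbitrary (a symmetry plane has an axial normal).

    This works for porous canopies where covariance-shape estimators fail:
    half a rosette is still nearly isotropic in plan view, but its
    visibility structure remembers the scan direction.
    """
    from scipy.spatial import cKDTree

    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > max_points:
        stride = int(np.ceil(len(pts) / max_points))
        pts = pts[::stride]
    # quasi-orthographic re-projection (distant virtual scanner) with
    # angular bins matched to ~3x the point spacing: a bin then spans a
    # small surface patch, so depth spread within a bin measures genuine
    # occlusion rather than surface curvature
    dist = 30.0
    spacing = float(np.median(cKDTree(pts).query(pts, k=2)[0][:, 1]))
    ang_tol = float(np.degrees(3.0 * max(spacing, 1e-6) / dist))
    azimuths = np.arange(0.0, 180.0, step_deg)
    f = np.array(
        [
            _self_occlusion(
                pts,
                np.array([np.cos(np.radians(a)), np.sin(np.radians(a)), 0.0]),
                ang_tol=ang_tol,
                dist=dist,
            )
            for a in azimuths
        ]
    )
    # the occlusion landscape is noisy at grid resolution; a circular
    # 3-tap smoothing keeps a spurious single-bin dip from winning
    fs = (np.roll(f, 1) + 2.0 * f + np.roll(f, -1)) / 4.0
    # near a solid shell's axis the landscape is a flat valley many bins
    # wide and the axis is the valley's center; a porous canopy gives a
    # narrow dip where the lowest bin itself is the best estimate
    thresh = fs.min() + 0.1 * max(float(np.ptp(fs)), 1e-12)
    n = len(fs)
    i0 = int(np.argmin(fs))
    lo = i0
    while fs[(lo - 1) % n] <= thresh and (i0 - lo) < n - 1:
        lo -= 1
    hi = i0
    while fs[(hi + 1) % n] <= thresh and (hi - i0) < n - 1:
        hi += 1
    if hi - lo + 1 >= 4:
        best_az = (azimuths[i0 % n] + step_deg * ((lo + hi) / 2.0 - i0)) % 180.0
    else:
        best_az = float(azimuths[i0])
    return np.array(
        [np.cos(np.radians(best_az)), np.sin(np.radians(best_az)), 0.0]
    )


def symmetry_complete(
    cloud: PointCloud,
    axis_hint: np.ndarray | None = None,
    rim_quantile: float = 0.98,
) -> tuple[PointCloud, SymmetryPlane]:
    """Mirror the visible side of a one-sided scan across a vertical plane.

    The (horizontal, axial) viewing direction is taken from ``axis_hint``
    when given — in practice the scanner position is acquisition metadata —
    and otherwise estimated by :func:`estimate_view_axis` from the cloud's
    self-occlusion structure.  The plane is positioned at the occlusion
    rim: the view-axis coordinate of the cloud's lateral and top extreme
    points, where the visible surface ends.  Points on the scanner side of
    the plane are reflected and appended, tagged ``synthetic = 1`` in the
    attrs.

    Returns the completed cloud and the estimated symmetry plane.  Raises
    for a degenerate (zero-horizontal-spread) cloud with no hint.
    """
    if len(cloud) == 0:
        raise ValueError("cannot complete an empty cloud")
    pts = cloud.points
    if axis_hint is not None:
        view = np.asarray(axis_hint, dtype=np.float64).copy()
        view[2] = 0.0
        norm = np.linalg.norm(view)
        if norm == 0:
            raise ValueError("axis_hint must have a horizontal component")
        view = view / norm
    else:
        if float(np.ptp(pts[:, 0])) < 1e-12 and float(np.ptp(pts[:, 1])) < 1e-12:
            raise ValueError(
                "cloud has no horizontal spread; pass axis_hint with the "
                "viewing direction"
            )
        view = estimate_view_axis(pts)
    # lateral axis: horizontal, perpendicular to the view axis
    major = np.array([-view[1], view[0], 0.0])

    # rim points: extremes along the in-plane horizontal axis and in height.
    # The occlusion boundary of a one-sided scan passes through them, so
    # their view-axis coordinate locates the symmetry plane.
    s_lat = pts @ major
    s_up = pts[:, 2]
    lat_lo, lat_hi = np.quantile(s_lat, [1 - rim_quantile, rim_quantile])
    up_hi = np.quantile(s_up, rim_quantile)
    rim = (s_lat <= lat_lo) | (s_lat >= lat_hi) | (s_up >= up_hi)
    # point the view axis toward the hidden side: the visible cloud's bulk
    # lies on the scanner side of the rim
    if float(np.mean(pts @ view)) > float(np.quantile(pts[rim] @ view, 0.9)):
        view = -view
    s = pts @ view
    # classify the cloud: a solid one-sided shell is about half as deep
    # (along the view) as it is wide, and is completed at the occlusion
    # rim; a porous canopy still spans its full depth (back surfaces show
    # through gaps — only their density drops), so its symmetry plane sits
    # at the center and mirroring merely densifies the sparse backside
    depth = np.quantile(s, 0.99) - np.quantile(s, 0.01)
    width = np.quantile(s_lat, 0.99) - np.quantile(s_lat, 0.01)
    if depth < 0.75 * width:
        offset = float(np.quantile(s[rim], 0.9))
    else:
        offset = float(np.median(s))
    centroid = pts.mean(axis=0)
    origin = centroid + (offset - centroid @ view) * view
    plane = SymmetryPlane(point=origin, normal=view)

    # mirror the visible side onto the hidden side
    visible = np.flatnonzero(s <= offset)
    mirrored = plane.mirror(pts[visible])

    all_pts = np.vstack([pts, mirrored])
    attrs = {}
    for name, col in cloud.attrs.items():
        attrs[name] = np.concatenate([col, col[visible]])
    attrs["synthetic"] = np.concatenate(
        [np.zeros(len(pts)), np.ones(len(mirrored))]
    )
    return PointCloud(all_pts, epoch=cloud.epoch, attrs=attrs), plane


def build_mesh(
    cloud: PointCloud,
    edge_tol: float | None = None,
    smooth_passes: int = 3,
    smooth_lambda: float = 0.5,
):
    """Delaunay-derived surface mesh with a simplified repair pass.

    The boundary triangles of the 3D Delaunay tetrahedralization form the
    raw surface; triangles with edges longer than ``edge_tol`` (default:
    4x the median edge) are removed, then vertex positions are Laplacian
    smoothed.  This is a deliberately simple stand-in for a full
    hole-filling mesh-repair stage, so the mesh is *not* guaranteed
    watertight; the returned :class:`trimesh.Trimesh` plus the flag in
    ``mesh.metadata['watertight']`` make that explicit.  The hull-volume
    quantities of the pipeline do not depend on mesh quality.
    """
    import trimesh

    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud)
    if len(pts) < 4:
        raise ValueError("mesh needs at least 4 points")
    try:
        tri = Delaunay(pts)
    except Exception as exc:
        raise ValueError(f"degenerate (coplanar?) input: {exc}") from None
    if tri.coplanar.size == len(pts) or tri.simplices.size == 0:
        raise ValueError("coplanar input has no enclosed volume")
    # boundary faces: tetra facets not shared by a neighboring tetra
    faces = []
    for s, nb in zip(tri.simplices, tri.neighbors):
        for f in range(4):
            if nb[f] == -1:
                faces.append(np.delete(s, f))
    faces = np.asarray(faces)
    mesh = trimesh.Trimesh(vertices=pts.copy(), faces=faces, process=True)
    if edge_tol is None:
        edge_tol = 4.0 * float(np.median(mesh.edges_unique_length))
    edge_len = np.linalg.norm(
        mesh.vertices[mesh.faces[:, [0, 1, 2]]]
        - mesh.vertices[mesh.faces[:, [1, 2, 0]]],
        axis=2,
    ).max(axis=1)
    mesh.update_faces(edge_len <= edge_tol)
    mesh.remove_unreferenced_vertices()
    mesh.fix_normals()
    if smooth_passes > 0 and len(mesh.vertices) > 0:
        # volume_constraint needs a signed volume, which an open mesh
        # cannot provide; plain Laplacian passes are used instead
        trimesh.smoothing.filter_laplacian(
            mesh,
            lamb=smooth_lambda,
            iterations=smooth_passes,
            volume_constraint=False,
        )
    mesh.metadata["watertight"] = bool(mesh.is_watertight)
    return mesh


def convex_hull_volume(points: np.ndarray | PointCloud) -> float:
    """Exact convex-hull volume of a point set, in dm³ (m³ x 1000)."""
    pts = points.points if isinstance(points, PointCloud) else np.asarray(points)
    if len(pts) < 4:
        raise ValueError("hull volume needs at least 4 points")
    try:
        hull = ConvexHull(pts)
    except Exception as exc:
        raise ValueError(f"degenerate (coplanar?) point set: {exc}") from None
    return float(hull.volume) * M3_TO_DM3


def build_canopy_model(
    cloud: PointCloud,
    complete: bool = True,
    axis_hint: np.ndarray | None = None,
    mesh: bool = True,
) -> CanopyModel:
    """Symmetry-complete (optionally), mesh and hull one epoch's canopy."""
    plane = None
    completed = cloud
    if complete:
        completed, plane = symmetry_complete(cloud, axis_hint=axis_hint)
    hull = ConvexHull(completed.points)
    notes: dict = {}
    if mesh:
        m = build_mesh(completed)
        verts, faces = np.asarray(m.vertices), np.asarray(m.faces)
        notes["mesh_watertight"] = bool(m.metadata.get("watertight", False))
        notes["mesh_area_m2"] = float(m.area)
    else:
        verts = completed.points
        faces = np.empty((0, 3), dtype=np.int64)
    return CanopyModel(
        completed_points=completed,
        mesh_vertices=verts,
        mesh_faces=faces,
        hull_vertices=hull.vertices,
        hull_volume=float(hull.volume) * M3_TO_DM3,
        epoch=cloud.epoch,
        watertight=notes.get("mesh_watertight", False),
        symmetry_plane=plane,
        notes=notes,
    )


def volume_change(models: list[CanopyModel] | list[float]) -> list[float]:
    """Signed per-interval volume deltas V(t+1) − V(t), in dm³.

    Accepts canopy models or plain per-epoch volumes in dm³, in temporal
    order; a negative delta means the canopy shrank (leaves closing).
    A single epoch yields an empty list.
    """
    vols = [
        m.hull_volume if isinstance(m, CanopyModel) else float(m) for m in models
    ]
    return [round(b - a, 10) for a, b in zip(vols[:-1], vols[1:])]
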