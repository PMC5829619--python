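"""Rigid alignment between epochs and cloud-to-cloud deviation maps.

The scanner stays put between acquisitions, but alignment is still verified
by a rigid-body (rotation + translation) registration.  The paper's sphere
targets are replaced here by Iterative Closest Point on the clouds
themselves (a static scene is assumed dominated by non-moving structure);
known target centroids can equally be fed to :func:`icp_rigid` as two small
clouds.

Movement between epochs is quantified by a two-stage deviation map: a
tree-accelerated chamfer (nearest-neighbor) pass, optionally refined by
fitting a local least-squares quadric surface to the reference cloud around
each compared point and measuring the point-to-surface distance.  The
quadric stage removes the sampling-discretization bias of nearest-neighbor
distances on smooth surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "RigidTransform",
    "DeviationMap",
    "icp_rigid",
    "apply_transform",
    "chamfer_deviation",
    "quadric_refined_deviation",
    "deviation_summary",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p ↦ R·p + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return RigidTransform(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class DeviationMap:
    """Unsigned per-point distances from a compared to a reference cloud."""

    distances: np.ndarray
    method: str
    reference_epoch: str = ""
    compared_epoch: str = ""
    #: number of compared points whose quadric fit was rank-deficient and
    #: fell back to the chamfer distance (0 for method="chamfer").
    n_fallback: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=np.float64)
        if np.any(d < 0):
            raise ValueError("deviation distances must be non-negative")
        self.distances = d


def _kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping paired source onto target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    H = (source - sc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, tc - R @ sc)


def icp_rigid(
    source: PointCloud,
    target: PointCloud,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[RigidTransform, float, bool]:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    Correspondences are nearest neighbors in a k-d tree; each iteration
    solves the closed-form least-squares rigid transform (SVD/Kabsch).
    The initial guess translates the source centroid onto the target
    centroid, which is adequate for the roughly prealigned epochs this
    pipeline sees.

    Returns ``(transform, residual, converged)`` where ``residual`` is the
    final mean absolute nearest-neighbor distance in meters.  When the
    change in residual never falls below ``tol`` within ``max_iter``
    iterations the best transform found is returned with
    ``converged=False``.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("ICP requires non-empty clouds")
    src = source.points
    tree = cKDTree(target.points)
    current = RigidTransform(np.eye(3), target.points.mean(0) - src.mean(0))
    prev_res = np.inf
    converged = False
    for _ in range(max_iter):
        moved = current.apply(src)
        dist, idx = tree.query(moved)
        step = _kabsch(moved, target.points[idx])
        current = step.compose(current)
        res = float(dist.mean())
        if abs(prev_res - res) < tol:
            converged = True
            break
        prev_res = res
    moved = current.apply(src)
    dist, _ = tree.query(moved)
    return current, float(np.abs(dist).mean()), converged


def apply_transform(cloud: PointCloud, t: RigidTransform) -> PointCloud:
    """p′ = R·p + t for every point; attrs and epoch preserved."""
    return cloud.with_points(t.apply(cloud.points))


def chamfer_deviation(compared: PointCloud, reference: PointCloud) -> DeviationMap:
    """Distance from each compared point to its nearest reference point.

    Tree-accelerated; identical (not just close) to the brute-force O(N²)
    nearest-neighbor computation.
    """
    if len(compared) == 0 or len(reference) == 0:
        raise ValueError("deviation needs two non-empty clouds")
    dist, _ = cKDTree(reference.points).query(compared.points)
    return DeviationMap(
        dist,
        method="chamfer",
        reference_epoch=reference.epoch,
        compared_epoch=compared.epoch,
    )


def _fit_quadric(local: np.ndarray) -> np.ndarray | None:
    """LSQ coefficients of z = a0 + a1 x + a2 y + a3 x² + a4 xy + a5 y²."""
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    A = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    coef, _, rank, _ = np.linalg.lstsq(A, z, rcond=None)
    if rank < 6:
        return None
    return coef

def _quadric_point_distance(
    coef: np.ndarray, p: np.ndarray, max_newton: int = 25
) -> float:
    """Distance from local-frame point ``p`` to the quadric graph surface.

    Minimizes ‖(u, v, q(u, v)) − p‖² by Gauss–Newton from the vertical
    projection (u, v) = (p_x, p_y); falls back to the plain vertical
    residual when the iteration does not improve (near-flat patches).
    """
    a0, a1, a2, a3, a4, a5 = coef

    def q(u, v):
        return a0 + a1 * u + a2 * v + a3 * u * u + a4 * u * v + a5 * v * v

    u, v = p[0], p[1]
    vertical = abs(q(u, v) - p[2])
    best = vertical
    for _ in range(max_newton):
        w = q(u, v)
        qu = a1 + 2 * a3 * u + a4 * v
        qv = a2 + a4 * u + 2 * a5 * v
        r = np.array([u - p[0], v - p[1], w - p[2]])
        # Jacobian of (u, v, q) wrt (u, v)
        J = np.array([[1.0, 0.0], [0.0, 1.0], [qu, qv]])
        g = J.T @ r
        H = J.T @ J
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        u, v = u - step[0], v - step[1]
        d = np.linalg.norm([u - p[0], v - p[1], q(u, v) - p[2]])
        if d < best:
            best = d
        if np.linalg.norm(step) < 1e-12:
            break
    return float(best)


def quadric_refined_deviation(
    compared: PointCloud,
    reference: PointCloud,
    neighborhood_k: int = 12,
) -> DeviationMap:
    """Point-to-locally-fitted-quadric distances, refined from chamfer.

    For each compared point the ``neighborhood_k`` nearest reference points
    are expressed in a local tangent frame (plane-fit axes from the
    neighborhood covariance); a bivariate quadric is least-squares fitted
    and the point-to-surface distance computed by Gauss–Newton projection.
    Rank-deficient fits fall back to the chamfer distance for that point
    and are counted in ``n_fallback``.
    """
    if neighborhood_k < 6:
        raise ValueError("neighborhood_k must be >= 6 (six quadric coefficients)")
    base = chamfer_deviation(compared, reference)
    k = min(neighborhood_k, len(reference))
    if k < 6:
        return DeviationMap(
            base.distances,
            method="quadric",
            reference_epoch=reference.epoch,
            compared_epoch=compared.epoch,
            n_fallback=len(compared),
        )
    tree = cKDTree(reference.points)
    _, nbr_idx = tree.query(compared.points, k=k)
    out = np.empty(len(compared))
    n_fallback = 0
    for i, p in enumerate(compared.points):
        nbrs = reference.points[nbr_idx[i]]
        center = nbrs.mean(axis=0)
        local_nbrs = nbrs - center
        cov = local_nbrs.T @ local_nbrs
        _, vecs = np.linalg.eigh(cov)
        # eigh: ascending eigenvalues -> columns [normal, tang2, tang1]
        axes = vecs[:, ::-1]  # tangent1, tangent2, normal
        coef = _fit_quadric(local_nbrs @ axes)
        if coef is None:
            out[i] = base.distances[i]
            n_fallback += 1
            continue
        d = _quadric_point_distance(coef, (p - center) @ axes)
        # chamfer caps the refinement: a quadric extrapolating beyond the
        # sampled patch cannot report more than the nearest-sample distance.
        out[i] = min(d, base.distances[i])
    return DeviationMap(
        out,
        method="quadric",
        reference_epoch=reference.epoch,
        compared_epoch=compared.epoch,
        n_fallback=n_fallback,
        extra={"chamfer_mean": float(base.distances.mean())},
    )


def deviation_summary(
    dev: DeviationMap, segment_labels: np.ndarray | None = None
) -> dict:
    """Global and optional per-leaf displacement statistics, in meters.

    With per-point labels the per-label mean/max are the per-leaf movement
    statistics (mean and maximum displacement of each leaf between the two
    epochs).
    """
    d = dev.distances
    out: dict = {"mean": float(d.mean()), "max": float(d.max()), "n": int(len(d))}
    if segment_labels is not None:
        labels = np.asarray(segment_labels)
        if len(labels) != len(d):
            raise ValueError("segment_labels length does not match deviation map")
        per_label = {}
        for lab in np.unique(labels):
            sel = d[labels == lab]
            per_label[int(lab)] = {
                "mean": float(sel.mean()),
                "max": float(sel.max()),
                "n": int(sel.size),
            }
        out["per_label"] = per_label
    return out
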