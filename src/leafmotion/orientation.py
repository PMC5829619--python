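"""Leaf orientation from PCA and its change over a day.

Each leaf's orientation is summarized by its principal normal: the
eigenvector of the leaf point cloud's covariance matrix

    Σ = (X − X̄)ᵀ (X − X̄) / k

with the smallest eigenvalue (the third principal component — the
direction in which a flat leaf has least extent).

Movement between acquisition times is characterized in spherical
coordinates on the *difference* of normals: for a difference vector
(x, y, z),

    θ = atan2(y, x)                    (azimuth / aspect, degrees)
    Φ = arctan( z / sqrt(x² + y²) )    (elevation / hyponasty, degrees)

atan2 keeps the full (−180°, 180°] azimuth range that plain arctan(y/x)
would collapse.  Both the per-consecutive-interval series and the
cumulative-versus-first-epoch series are emitted, since either convention
is a legitimate trajectory reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import LeafSegment, LeafTrack, canonicalize_signs

__all__ = [
    "OrientationChange",
    "leaf_normal_pca",
    "spherical_angles",
    "orientation_change",
]

#: a normal difference below this (unit-normal units) is treated as no motion
NULL_DELTA = 1e-9


@dataclass(frozen=True)
class OrientationChange:
    """Orientation change of one leaf over one time interval."""

    leaf_id: int
    interval: tuple[str, str]
    delta_vector: np.ndarray  # n_later - n_earlier
    theta: float | None  # degrees in (-180, 180]; None for a null interval
    phi: float | None  # degrees in [-90, 90]
    cumulative: bool = False  # True: interval measured from the first epoch


def leaf_normal_pca(segment: LeafSegment | np.ndarray) -> np.ndarray:
    """Principal leaf normal: smallest-eigenvalue eigenvector of Σ.

    Accepts a :class:`LeafSegment` or a raw ``(k, 3)`` coordinate array.
    The sign is canonicalized into the +z hemisphere (ties toward +x).
    Raises for rank-deficient (collinear) segments.
    """
    pts = segment.points if isinstance(segment, LeafSegment) else np.asarray(segment)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise ValueError("leaf_normal_pca needs a (k>=3, 3) coordinate array")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    vals, vecs = np.linalg.eigh(cov)
    if vals[1] <= 1e-12 * max(vals[2], 1e-300):
        name = (
            f"leaf {segment.leaf_id}" if isinstance(segment, LeafSegment) else "segment"
        )
        raise ValueError(f"{name}: points are collinear, normal undefined")
    return canonicalize_signs(vecs[:, 0][None])[0]


def spherical_angles(v: np.ndarray) -> tuple[float, float]:
    """(azimuth θ, elevation Φ) of a 3-vector, in degrees.

    θ = atan2(y, x) ∈ (−180, 180]; Φ = arctan(z / √(x²+y²)) ∈ [−90, 90].
    On the poles (x = y = 0) θ is defined as 0 and Φ as ±90.
    """
    v = np.asarray(v, dtype=np.float64).reshape(3)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("spherical angles of the zero vector are undefined")
    x, y, z = v
    horiz = np.hypot(x, y)
    if horiz == 0:
        return 0.0, float(np.copysign(90.0, z))
    theta = float(np.degrees(np.arctan2(y, x)))
    if theta <= -180.0:
        theta = 180.0
    phi = float(np.degrees(np.arctan(z / horiz)))
    return theta, phi


def orientation_change(
    track: LeafTrack,
    normals_by_epoch: dict[str, np.ndarray] | None = None,
    epoch_order: list[str] | None = None,
) -> list[OrientationChange]:
    """Per-interval and cumulative orientation changes along a leaf track.

    Normals default to each segment's PCA normal; ``normals_by_epoch`` can
    override (e.g. with ground-truth normals).  For every consecutive epoch
    pair, and additionally for every later epoch versus the first
    (``cumulative=True`` entries), the difference of unit normals is taken
    in temporal order and converted to (θ, Φ).  A vanishing difference is
    reported as a null interval with angles ``None``.
    """
    epochs = epoch_order if epoch_order is not None else list(track.segments)
    epochs = [e for e in epochs if e in track.segments]
    if len(epochs) < 2:
        raise ValueError("orientation change needs a track spanning >= 2 epochs")

    def raw_normal(epoch: str) -> np.ndarray:
        if normals_by_epoch is not None and epoch in normals_by_epoch:
            n = np.asarray(normals_by_epoch[epoch], dtype=np.float64)
        else:
            n = track.segments[epoch].pca_normal
        return n / np.linalg.norm(n)

    # PCA normals are axial (sign-free); chain signs in temporal order so
    # each epoch's normal points the same way the previous one did — a
    # leaf tilting past the horizontal must not appear to jump hemispheres
    aligned: dict[str, np.ndarray] = {}
    prev = None
    for e in epochs:
        n = raw_normal(e)
        if prev is not None and n @ prev < 0:
            n = -n
        aligned[e] = n
        prev = n

    out: list[OrientationChange] = []

    def emit(e_from: str, e_to: str, cumulative: bool) -> None:
        delta = aligned[e_to] - aligned[e_from]
        if np.linalg.norm(delta) < NULL_DELTA:
            theta = phi = None
        else:
            theta, phi = spherical_angles(delta)
        out.append(
            OrientationChange(
                leaf_id=track.leaf_id,
                interval=(e_from, e_to),
                delta_vector=delta,
                theta=theta,
                phi=phi,
                cumulative=cumulative,
            )
        )

    for e_from, e_to in zip(epochs[:-1], epochs[1:]):
        emit(e_from, e_to, cumulative=False)
    for e_to in epochs[2:]:
        emit(epochs[0], e_to, cumulative=True)
    return out


def changes_to_frame(changes: list[OrientationChange]):
    """Tabulate orientation changes (one row per leaf and interval)."""
    import pandas as pd

    rows = []
    for ch in changes:
        dx, dy, dz = ch.delta_vector
        rows.append(
            {
                "leaf_id": ch.leaf_id,
                "epoch_from": ch.interval[0],
                "epoch_to": ch.interval[1],
                "cumulative": ch.cumulative,
                "dx": dx,
                "dy": dy,
                "dz": dz,
                "theta_deg": ch.theta,
                "phi_deg": ch.phi,
            }
        )
    return pd.DataFrame(rows)


def plot_trajectories(changes: list[OrientationChange], path: str) -> None:
    """Quiver-style trajectory plot: azimuth change (x) vs vertical-angle
    change (y), one polyline of interval points per leaf."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    by_leaf: dict[int, list[OrientationChange]] = {}
    for ch in changes:
        if not ch.cumulative and ch.theta is not None:
            by_leaf.setdefault(ch.leaf_id, []).append(ch)
    for leaf_id, chs in sorted(by_leaf.items()):
        xs = [c.theta for c in chs]
        ys = [c.phi for c in chs]
        ax.plot(xs, ys, marker="o", label=f"leaf {leaf_id}")
        if len(xs) >= 2:
            ax.annotate(
                "",
                xy=(xs[-1], ys[-1]),
                xytext=(xs[-2], ys[-2]),
                arrowprops=dict(arrowstyle="->"),
            )
    ax.set_xlabel("azimuth change θ (deg)")
    ax.set_ylabel("vertical angle change Φ (deg)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
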