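"""Point-cloud container, ASCII I/O and the common analysis frame.

The pipeline's universal currency is a :class:`PointCloud`: an ordered
``(N, 3)`` array of coordinates in meters, an epoch label (e.g. ``"07:00"``)
and optional named per-point scalar attributes (intensity, leaf label, ...).

Supported on-disk dialects are deliberately human-inspectable: ASCII PLY
(``element vertex`` with ``x y z`` float properties plus one property per
attribute) and whitespace/comma-delimited XYZ/CSV.  Binary PLY and scanner
vendor formats are out of scope.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointCloud",
    "BoundingBox",
    "read_cloud",
    "write_cloud",
    "common_bbox_crop",
]

#: 17 significant digits round-trip an IEEE double exactly, so every ASCII
#: dialect reproduces coordinates bit-for-bit
_ASCII_FMT = "%.17g"


class CloudFormatError(ValueError):
    """Raised when a cloud file does not parse in the named dialect."""


@dataclass
class PointCloud:
    """An ordered set of 3D points in meters with optional per-point attrs."""

    points: np.ndarray
    epoch: str = ""
    attrs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite coordinates")
        self.points = pts
        clean = {}
        for name, col in self.attrs.items():
            col = np.asarray(col)
            if col.shape != (len(pts),):
                raise ValueError(
                    f"attr {name!r} has shape {col.shape}, expected ({len(pts)},)"
                )
            clean[name] = col
        self.attrs = clean

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray, epoch: str | None = None) -> "PointCloud":
        """Subset (or reorder) by integer/boolean index, attrs carried along."""
        return PointCloud(
            self.points[index],
            epoch=self.epoch if epoch is None else epoch,
            attrs={k: v[index] for k, v in self.attrs.items()},
        )

    def with_points(self, points: np.ndarray) -> "PointCloud":
        """Same metadata/attrs, new coordinates (same point count)."""
        if len(points) != len(self):
            raise ValueError("with_points requires identical point count")
        return PointCloud(points, epoch=self.epoch, attrs=dict(self.attrs))

    def bounding_box(self) -> "BoundingBox":
        if len(self) == 0:
            raise ValueError("empty cloud has no bounding box")
        return BoundingBox(self.points.min(axis=0), self.points.max(axis=0))


@dataclass
class BoundingBox:
    """Axis-aligned box, corners in meters."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    def __post_init__(self) -> None:
        self.min_corner = np.asarray(self.min_corner, dtype=np.float64).reshape(3)
        self.max_corner = np.asarray(self.max_corner, dtype=np.float64).reshape(3)
        if np.any(self.min_corner > self.max_corner):
            raise ValueError("min_corner must be <= max_corner componentwise")

    def expanded(self, padding: float) -> "BoundingBox":
        return BoundingBox(self.min_corner - padding, self.max_corner + padding)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean inclusion mask (closed box)."""
        pts = np.asarray(points, dtype=np.float64)
        return np.all((pts >= self.min_corner) & (pts <= self.max_corner), axis=1)

    @staticmethod
    def intersection(boxes: list["BoundingBox"]) -> "BoundingBox":
        lo = np.max([b.min_corner for b in boxes], axis=0)
        hi = np.min([b.max_corner for b in boxes], axis=0)
        if np.any(lo > hi):
            raise ValueError(
                "bounding boxes do not intersect; check that all epochs are "
                "registered into a common frame"
            )
        return BoundingBox(lo, hi)


# ---------------------------------------------------------------------------
# readers / writers


def _infer_format(path: str, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = os.path.splitext(path)[1].lstrip(".").lower() or "xyz"
        if fmt == "txt":
            fmt = "xyz"
    if fmt not in ("ply", "xyz", "csv"):
        raise CloudFormatError(f"unknown point-cloud format {fmt!r}")
    return fmt


def read_cloud(path: str, format: str | None = None, epoch: str = "") -> PointCloud:
    """Read a point cloud from ASCII PLY, XYZ or CSV.

    Parameters
    ----------
    path
        File to read.
    format
        ``"ply"``, ``"xyz"`` or ``"csv"``; inferred from the extension when
        omitted.
    epoch
        Epoch label to stamp on the returned cloud.
    """
    fmt = _infer_format(path, format)
    if fmt == "ply":
        return _read_ply(path, epoch)
    return _read_xyz(path, epoch, delimiter="," if fmt == "csv" else None)


def write_cloud(cloud: PointCloud, path: str, format: str | None = None) -> None:
    """Write a cloud so that :func:`read_cloud` round-trips it exactly.

    Attributes are preserved in all three dialects (extra PLY vertex
    properties; extra delimited columns after a header line for xyz/csv).
    """
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path)
    else:
        _write_xyz(cloud, path, delimiter="," if fmt == "csv" else " ")


def _read_ply(path: str, epoch: str) -> PointCloud:
    with open(path, "r") as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise CloudFormatError(f"{path}: not a PLY file (missing 'ply' magic)")
        n_vertex = None
        props: list[str] = []
        in_vertex = False
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise CloudFormatError(f"{path}: unexpected EOF in header")
            tok = line.split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                if tok[1] != "ascii":
                    raise CloudFormatError(f"{path}: only ASCII PLY is supported")
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        if n_vertex is None:
            raise CloudFormatError(f"{path}: header declares no vertex element")
        for axis in ("x", "y", "z"):
            if axis not in props:
                raise CloudFormatError(f"{path}: vertex element lacks property {axis}")
        rows = np.empty((n_vertex, len(props)), dtype=np.float64)
        for i in range(n_vertex):
            line = fh.readline()
            lineno += 1
            vals = line.split()
            if len(vals) != len(props):
                raise CloudFormatError(
                    f"{path}:{lineno}: expected {len(props)} values, got {len(vals)}"
                )
            try:
                rows[i] = [float(v) for v in vals]
            except ValueError as exc:
                raise CloudFormatError(f"{path}:{lineno}: {exc}") from None
    cols = {name: rows[:, j] for j, name in enumerate(props)}
    pts = np.column_stack([cols.pop("x"), cols.pop("y"), cols.pop("z")])
    return PointCloud(pts, epoch=epoch, attrs=cols)


def _write_ply(cloud: PointCloud, path: str) -> None:
    names = list(cloud.attrs)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment produced by leafmotion\n")
        fh.write(f"element vertex {len(cloud)}\n")
        for axis in ("x", "y", "z"):
            fh.write(f"property double {axis}\n")
        for name in names:
            fh.write(f"property double {name}\n")
        fh.write("end_header\n")
        table = cloud.points
        if names:
            table = np.column_stack(
                [table] + [np.asarray(cloud.attrs[n], dtype=np.float64) for n in names]
            )
        np.savetxt(fh, table, fmt=_ASCII_FMT)


def _read_xyz(path: str, epoch: str, delimiter: str | None) -> PointCloud:
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                # a leading "# x y z ..." comment documents the columns
                tok = line.lstrip("#").split()
                if header is None and not rows and {"x", "y", "z"} <= set(tok):
                    header = tok
                continue
            tok = line.split(delimiter)
            tok = [t.strip() for t in tok if t.strip() != ""]
            try:
                rows.append([float(t) for t in tok])
            except ValueError:
                if header is None and not rows:
                    header = tok
                    continue
                raise CloudFormatError(
                    f"{path}:{lineno}: non-numeric record {line!r}"
                ) from None
            if len(rows[-1]) < 3:
                raise CloudFormatError(f"{path}:{lineno}: fewer than 3 coordinates")
    if not rows:
        return PointCloud(np.empty((0, 3)), epoch=epoch)
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise CloudFormatError(f"{path}: inconsistent column count")
    arr = np.asarray(rows, dtype=np.float64)
    if header is None:
        header = ["x", "y", "z"] + [f"c{j}" for j in range(3, width)]
    if len(header) != width:
        raise CloudFormatError(f"{path}: header/data column mismatch")
    cols = {name: arr[:, j] for j, name in enumerate(header)}
    try:
        pts = np.column_stack([cols.pop("x"), cols.pop("y"), cols.pop("z")])
    except KeyError:
        pts, cols = arr[:, :3], {h: arr[:, j] for j, h in enumerate(header) if j >= 3}
    return PointCloud(pts, epoch=epoch, attrs=cols)


def _write_xyz(cloud: PointCloud, path: str, delimiter: str) -> None:
    names = list(cloud.attrs)
    table = cloud.points
    if names:
        table = np.column_stack(
            [table] + [np.asarray(cloud.attrs[n], dtype=np.float64) for n in names]
        )
    with open(path, "w") as fh:
        if delimiter == ",":
            fh.write(",".join(["x", "y", "z"] + names) + "\n")
        elif names:  # xyz with attrs: comment header documents the columns
            fh.write("# " + " ".join(["x", "y", "z"] + names) + "\n")
        np.savetxt(fh, table, fmt=_ASCII_FMT, delimiter=delimiter)


def read_labels(path: str, n_points: int | None = None) -> np.ndarray:
    """Read a ``point_index,label`` CSV into a dense integer label vector."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"point_index", "label"} <= set(df.columns):
        raise CloudFormatError(f"{path}: expected columns point_index,label")
    idx = df["point_index"].to_numpy(dtype=np.int64)
    n = int(idx.max()) + 1 if n_points is None else n_points
    out = np.zeros(n, dtype=np.int64)
    out[idx] = df["label"].to_numpy(dtype=np.int64)
    return out


def write_labels(labels: np.ndarray, path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {"point_index": np.arange(len(labels)), "label": np.asarray(labels)}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# common analysis frame


def common_bbox_crop(
    clouds: list[PointCloud], padding: float = 0.02
) -> list[PointCloud]:
    """Crop every epoch to one shared axis-aligned box.

    The shared box is the *intersection* of the per-cloud bounding boxes,
    expanded by ``padding`` meters on every side, so all epochs cover the
    same region of space before deviation maps are computed.  Retained
    points keep their original order; attrs are carried along.
    """
    if not clouds:
        raise ValueError("need at least one cloud")
    for c in clouds:
        if len(c) == 0:
            raise ValueError("common_bbox_crop requires non-empty clouds")
    box = BoundingBox.intersection([c.bounding_box() for c in clouds]).expanded(padding)
    return [c.select(np.flatnonzero(box.contains(c.points))) for c in clouds]
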