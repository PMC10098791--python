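"""Point-cloud container, file I/O, canonical body frame, and turntable merging.

Conventions
-----------
All coordinates are in meters, in the *canonical body frame*:

* ``y`` — vertical axis, feet at ``y = 0``;
* ``z`` — sagittal axis, the subject faces ``+z`` (buttocks and calf bulge
  at small/negative ``z``);
* ``x`` — transversal axis, centered so the body midline is near ``x = 0``
  (the subject's right side is at negative ``x``).

Supported file formats: PLY (ascii and binary little-endian, via trimesh),
PCD v0.7 ascii, and plain whitespace XYZ text.
"""

from __future__ import annotations

import os
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyCloudError, FormatError, ValidationError

__all__ = [
    "PointCloud",
    "TurntableCapture",
    "read_pointcloud",
    "write_pointcloud",
    "canonicalize",
    "merge_turntable_scans",
    "voxel_downsample",
]


@dataclass(frozen=True)
class PointCloud:
    """An unordered set of 3D points, shape ``(n, 3)``, meters."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (n, 3), got {pts.shape}")
        if pts.size and not np.isfinite(pts).all():
            raise ValidationError("point coordinates must be finite")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def require_nonempty(self, what: str = "operation") -> None:
        if len(self) == 0:
            raise EmptyCloudError(f"{what} requires a non-empty point cloud")

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    def translated(self, offset: Sequence[float]) -> "PointCloud":
        return PointCloud(self.points + np.asarray(offset, dtype=np.float64))

    def scaled(self, s: float) -> "PointCloud":
        if s <= 0:
            raise ValidationError("scale factor must be positive")
        return PointCloud(self.points * float(s))


@dataclass(frozen=True)
class TurntableCapture:
    """Partial scans taken on a rotating platform at known angles.

    ``angles_deg[i]`` is the platform rotation (degrees, in ``[0, 360)``,
    strictly increasing) at which ``frames[i]`` was captured.
    """

    frames: list[PointCloud]
    angles_deg: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.angles_deg):
            raise ValidationError(
                f"{len(self.frames)} frames but {len(self.angles_deg)} angles"
            )
        if len(self.frames) == 0:
            raise ValidationError("capture needs at least one frame")
        ang = np.asarray(self.angles_deg, dtype=np.float64)
        if np.any(ang < 0) or np.any(ang >= 360):
            raise ValidationError("angles must lie in [0, 360) degrees")
        if np.any(np.diff(ang) <= 0):
            raise ValidationError("angles must be strictly increasing")


# ---------------------------------------------------------------------------
# File I/O


def _detect_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("ply", "pcd", "xyz"):
        return ext
    if ext in ("txt", "asc"):
        return "xyz"
    raise FormatError(f"cannot infer point-cloud format from {path!r}")


def _read_ply(path: str) -> np.ndarray:
    try:
        obj = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"unreadable PLY file {path!r}: {exc}") from exc
    verts = np.asarray(obj.vertices, dtype=np.float64)
    return verts.reshape(-1, 3)


def _read_pcd(path: str) -> np.ndarray:
    """Minimal PCD v0.7 ascii reader (x, y, z fields; others ignored)."""
    header: dict[str, list[str]] = {}
    data_rows: list[list[float]] = []
    with open(path, encoding="utf-8") as fh:
        in_data = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not in_data:
                key, *vals = line.split()
                header[key.upper()] = vals
                if key.upper() == "DATA":
                    if vals and vals[0].lower() != "ascii":
                        raise FormatError("only DATA ascii PCD files are supported")
                    in_data = True
                continue
            data_rows.append([float(v) for v in line.split()])
    if "FIELDS" not in header or not in_data:
        raise FormatError(f"{path!r} is not a valid ascii PCD file")
    fields = [f.lower() for f in header["FIELDS"]]
    try:
        cols = [fields.index(ax) for ax in ("x", "y", "z")]
    except ValueError as exc:
        raise FormatError("PCD file lacks x/y/z fields") from exc
    if not data_rows:
        return np.empty((0, 3))
    arr = np.asarray(data_rows, dtype=np.float64)
    return arr[:, cols]


def _read_xyz(path: str) -> np.ndarray:
    try:
        arr = np.loadtxt(path, comments="#", ndmin=2, dtype=np.float64)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable XYZ file {path!r}: {exc}") from exc
    if arr.size == 0:
        return np.empty((0, 3))
    if arr.shape[1] < 3:
        raise FormatError(f"XYZ file {path!r} has fewer than 3 columns")
    return arr[:, :3]


def read_pointcloud(path: str, format: str = "auto") -> PointCloud:
    """Read a point cloud; color/normal attributes are ignored.

    Parameters
    ----------
    path : str
        Input file.
    format : {"auto", "ply", "pcd", "xyz"}
        ``auto`` infers from the file extension.
    """
    if not os.path.isfile(path):
        raise FormatError(f"no such file: {path!r}")
    fmt = _detect_format(path) if format == "auto" else format.lower()
    if fmt == "ply":
        pts = _read_ply(path)
    elif fmt == "pcd":
        pts = _read_pcd(path)
    elif fmt == "xyz":
        pts = _read_xyz(path)
    else:
        raise FormatError(f"unknown format {format!r}")
    if pts.shape[0] == 0:
        raise EmptyCloudError(f"{path!r} contains no points")
    return PointCloud(pts)


def write_pointcloud(
    cloud: PointCloud, path: str, format: str = "auto", encoding: str = "binary"
) -> None:
    """Write a point cloud to PLY, PCD (ascii) or XYZ.

    ``encoding`` applies to PLY only: ``"binary"`` (little-endian) or
    ``"ascii"``.
    """
    cloud.require_nonempty("write_pointcloud")
    fmt = _detect_format(path) if format == "auto" else format.lower()
    if fmt == "ply":
        pc = trimesh.points.PointCloud(cloud.points)
        enc = "binary_little_endian" if encoding == "binary" else "ascii"
        data = trimesh.exchange.ply.export_ply(pc, encoding=enc)
        with open(path, "wb") as fh:
            fh.write(data)
    elif fmt == "pcd":
        n = len(cloud)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# .PCD v0.7 - Point Cloud Data file format\n")
            fh.write("VERSION 0.7\nFIELDS x y z\nSIZE 8 8 8\nTYPE F F F\n")
            fh.write(f"COUNT 1 1 1\nWIDTH {n}\nHEIGHT 1\n")
            fh.write(f"VIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n")
            np.savetxt(fh, cloud.points, fmt="%.9g")
    elif fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.9g")
    else:
        raise FormatError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Canonical frame and merging


def canonicalize(cloud: PointCloud) -> PointCloud:
    """Translate the cloud into the canonical body frame.

    The minimum ``y`` becomes 0 (feet on the floor) and the centroid of the
    ``x``/``z`` coordinates moves to the origin. The axes themselves are
    *not* re-estimated: the input must already be axis-aligned (y vertical,
    z sagittal, x transversal).
    """
    cloud.require_nonempty("canonicalize")
    pts = cloud.points
    offset = np.array(
        [pts[:, 0].mean(), pts[:, 1].min(), pts[:, 2].mean()], dtype=np.float64
    )
    return PointCloud(pts - offset)


def _rot_y(angle_deg: float) -> np.ndarray:
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def merge_turntable_scans(
    capture: TurntableCapture,
    refine: Callable[[PointCloud], PointCloud] | None = None,
) -> PointCloud:
    """Undo the known platform rotation of each frame and concatenate.

    Each frame is rotated about the vertical axis by ``-angle`` so that all
    frames land in the platform's reference orientation. ``refine`` is an
    optional fine-registration hook (e.g. an ICP pass) applied to the merged
    cloud; by default the merge relies purely on the known angles.
    """
    parts = []
    for frame, angle in zip(capture.frames, capture.angles_deg):
        frame.require_nonempty("merge_turntable_scans")
        parts.append(frame.points @ _rot_y(-angle).T)
    merged = PointCloud(np.vstack(parts))
    if refine is not None:
        merged = refine(merged)
    return merged


def voxel_downsample(cloud: PointCloud, voxel_m: float) -> PointCloud:
    """Replace all points within each ``voxel_m`` cube by their centroid."""
    if voxel_m <= 0:
        raise ValidationError("voxel_m must be positive")
    cloud.require_nonempty("voxel_downsample")
    pts = cloud.points
    origin = pts.min(axis=0)
    # tiny nudge so points sitting exactly on a voxel boundary (within float
    # error) quantize consistently
    keys = np.floor((pts - origin) / voxel_m + 1e-9).astype(np.int64)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_voxels = inverse.max() + 1
    sums = np.zeros((n_voxels, 3))
    np.add.at(sums, inverse, pts)
    counts = np.bincount(inverse, minlength=n_voxels).astype(np.float64)
    return PointCloud(sums / counts[:, None])
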