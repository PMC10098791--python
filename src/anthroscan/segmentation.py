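"""Landmark-driven segmentation of a canonical T-pose scan into 9 body parts.

The procedure mirrors how a human figure is carved up for tape-measure
anthropometry:

1. the hip landmark ``PH`` is the rear-most point (smallest sagittal ``z``)
   in a horizontal band around the cloud's geometric center — on an adult
   standing figure that band straddles the buttocks;
2. ``PH.y`` is both the hip-girth plane and the upper/lower body divide;
3. the lateral midline ``xH`` is the midpoint of the transversal extremes
   in a thin band around ``PH.y`` and splits left from right;
4. knees are placed by body-segment proportions, splitting thighs from
   lower legs;
5. the upper body is projected to the XY plane, its outline extracted with a
   concave hull (alpha shape), and the armpit/shoulder junction points
   (``PRAdown``/``PRAup`` on the subject's right, ``PLAdown``/``PLAup`` on
   the left) are found by walking each side's outline upward from the lowest
   points until a step vector turns lateral;
6. the junctions delimit arms, head and torso; the torso is split in half
   into upper and lower torso.

All thresholds live in :class:`SegmentationConfig`. The proportion constants
are standard adult segment ratios and are deliberately configurable: they
are calibration inputs, not universal constants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from enum import IntEnum

import numpy as np
from scipy.spatial import Delaunay

from .errors import (
    ContourError,
    LandmarkError,
    NoArmFoundError,
    ValidationError,
)
from .pointcloud import PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "BodySegment",
    "SegmentationConfig",
    "SegmentationLandmarks",
    "ContourPolyline",
    "SegmentedScan",
    "concave_hull_2d",
    "find_hip_point",
    "compute_lateral_midline",
    "split_upper_lower",
    "estimate_knee_height",
    "upper_body_contour",
    "find_arm_junctions",
    "assign_segments",
    "segment_body",
    "write_segmented_scan",
    "write_landmarks",
]


class BodySegment(IntEnum):
    """The nine body-part labels."""

    HEAD = 0
    UPPER_TORSO = 1
    LOWER_TORSO = 2
    RIGHT_ARM = 3
    LEFT_ARM = 4
    RIGHT_THIGH = 5
    LEFT_THIGH = 6
    RIGHT_LOWER_LEG = 7
    LEFT_LOWER_LEG = 8


# fields of SegmentationConfig that carry units of meters
_LENGTH_FIELDS = (
    "thH",
    "thcut",
    "hip_band_halfwidth",
    "concave_alpha",
    "eps_x",
    "contour_step",
    "min_arm_extent",
)


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds and body-proportion constants.

    Lengths are in meters and assume a subject of roughly adult stature
    scanned at millimeter-scale point spacing; use :meth:`scaled` when
    processing a uniformly rescaled cloud. Fractions are dimensionless.
    """

    thH: float = 0.02  # half-height of the lateral-midline band, m
    thdir: float = 0.5  # |x|-component threshold on unit contour steps
    thcut: float = 0.01  # half-thickness of measurement slabs, m
    hip_band_halfwidth: float = 0.05  # hip-search band around the centroid, m
    concave_alpha: float = 0.02  # alpha-shape characteristic length, m
    eps_x: float = 0.01  # x-tolerance matching junction-up to junction-down, m
    contour_step: float = 0.01  # resampling step along the outline walk, m
    min_arm_extent: float = 0.05  # minimum lateral reach of a detected arm, m

    knee_height_frac: float = 0.285  # knee height / stature
    hip_height_frac: float = 0.53  # hip height / stature
    shoulder_height_frac: float = 0.81  # shoulder height / stature
    waist_frac_of_torso: float = 0.35  # waist above hip / hip→neck distance
    upperarm_frac_of_arm: float = 0.56  # upper-arm length / whole-arm length
    calf_search_band: float = 0.3  # half-width of the calf search band,
    # as a fraction of the lower-leg span around its midpoint

    min_contour_points: int = 10

    def __post_init__(self) -> None:
        for name in _LENGTH_FIELDS:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.thdir < 1:
            raise ValidationError("thdir must be in (0, 1)")
        for name in (
            "knee_height_frac",
            "hip_height_frac",
            "shoulder_height_frac",
            "waist_frac_of_torso",
            "upperarm_frac_of_arm",
            "calf_search_band",
        ):
            if not 0 < getattr(self, name) < 1:
                raise ValidationError(f"{name} must be in (0, 1)")

    def scaled(self, s: float) -> "SegmentationConfig":
        """Config for a cloud uniformly scaled by ``s`` (lengths scale too)."""
        if s <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(self, **{n: getattr(self, n) * s for n in _LENGTH_FIELDS})

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f in fields(self):
                fh.write(f"{f.name}: {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str) -> "SegmentationConfig":
        kwargs: dict[str, float | int] = {}
        names = {f.name: f for f in fields(cls)}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, sep, raw = line.partition(":")
                key = key.strip()
                if not sep or key not in names:
                    raise ValidationError(
                        f"{path}:{lineno}: unknown config entry {line!r}"
                    )
                cast = int if names[key].type is int else float
                kwargs[key] = cast(float(raw))
        return cls(**kwargs)


@dataclass(frozen=True)
class SegmentationLandmarks:
    """Derived anchor points, meters, canonical frame."""

    PH: tuple[float, float, float]  # hip point (rear-most in the hip band)
    xH: float  # lateral midline
    hip_y: float  # hip-girth plane == PH.y
    knee_y_right: float
    knee_y_left: float
    PRAdown: tuple[float, float]  # right armpit (XY projection)
    PRAup: tuple[float, float]  # right shoulder top
    PLAdown: tuple[float, float]
    PLAup: tuple[float, float]
    shoulder_y: float
    torso_split_y: float

    def __post_init__(self) -> None:
        if not (self.PRAdown[1] < self.PRAup[1] and self.PLAdown[1] < self.PLAup[1]):
            raise ValidationError("junction-down must lie below junction-up")
        if not (self.PRAdown[0] < self.xH < self.PLAdown[0]):
            raise ValidationError("arm junctions must straddle the midline xH")


@dataclass(frozen=True)
class ContourPolyline:
    """Closed outline of the upper-body XY projection (first==last implied)."""

    vertices: np.ndarray  # (m, 2), ordered counter-clockwise

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValidationError("contour needs at least 3 (x, y) vertices")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class SegmentedScan:
    cloud: PointCloud
    labels: np.ndarray  # (n,) BodySegment values
    landmarks: SegmentationLandmarks

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.shape != (len(self.cloud),):
            raise ValidationError("labels must align with cloud points")
        object.__setattr__(self, "labels", labels)

    def segment(self, label: BodySegment) -> PointCloud:
        return PointCloud(self.cloud.points[self.labels == label])

    def counts(self) -> dict[BodySegment, int]:
        return {seg: int(np.sum(self.labels == seg)) for seg in BodySegment}


# ---------------------------------------------------------------------------
# Concave hull (alpha shape)


def concave_hull_2d(points: np.ndarray, alpha: float) -> np.ndarray:
    """Ordered boundary (CCW) of the alpha shape of a dense 2D point set.

    Delaunay triangles with circumradius above ``alpha`` are discarded; the
    boundary is the closed loop of edges that belong to exactly one remaining
    triangle. If several loops survive (holes, fragments) the one enclosing
    the largest area is returned.
    """
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    if pts.shape[0] < 4:
        raise ContourError("too few distinct points for a concave hull")
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # noqa: BLE001 - qhull failures (collinear etc.)
        raise ContourError(f"degenerate point set: {exc}") from exc

    simp = tri.simplices
    p0, p1, p2 = pts[simp[:, 0]], pts[simp[:, 1]], pts[simp[:, 2]]
    la = np.linalg.norm(p1 - p0, axis=1)
    lb = np.linalg.norm(p2 - p1, axis=1)
    lc = np.linalg.norm(p0 - p2, axis=1)
    u, v = p1 - p0, p2 - p0
    area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])  # 2 * triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = la * lb * lc / (2.0 * area2)
    keep = (area2 > 1e-300) & (circum_r <= alpha)
    if not keep.any():
        raise ContourError("alpha too small: no triangle survives")

    edges: dict[tuple[int, int], int] = {}
    for s in simp[keep]:
        for i, j in ((s[0], s[1]), (s[1], s[2]), (s[2], s[0])):
            key = (i, j) if i < j else (j, i)
            edges[key] = edges.get(key, 0) + 1
    boundary = [e for e, c in edges.items() if c == 1]
    if len(boundary) < 3:
        raise ContourError("no closed boundary in alpha shape")

    adj: dict[int, list[int]] = {}
    for i, j in boundary:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)

    unused = {tuple(sorted(e)) for e in boundary}
    loops: list[list[int]] = []
    while unused:
        i0, j0 = next(iter(unused))
        loop = [i0, j0]
        unused.discard((min(i0, j0), max(i0, j0)))
        prev, cur = i0, j0
        while True:
            nxt = None
            for cand in adj[cur]:
                key = (min(cur, cand), max(cur, cand))
                if cand != prev and key in unused:
                    nxt = cand
                    unused.discard(key)
                    break
            if nxt is None or nxt == loop[0]:
                break
            loop.append(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(loop)
    if not loops:
        raise ContourError("boundary edges do not form a loop")

    def shoelace(idx: list[int]) -> float:
        v = pts[idx]
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )

    areas = [shoelace(lp) for lp in loops]
    best = int(np.argmax(np.abs(areas)))
    loop = loops[best]
    if areas[best] < 0:  # orient counter-clockwise
        loop = loop[::-1]
    return pts[loop]


# ---------------------------------------------------------------------------
# Landmarks


def find_hip_point(
    cloud: PointCloud, config: SegmentationConfig
) -> tuple[tuple[float, float, float], float]:
    """Locate the hip landmark ``PH`` and the hip-girth plane height.

    The geometric center (point centroid) approximates the hip height on a
    standing figure; within ``hip_band_halfwidth`` of it, the point with the
    smallest sagittal coordinate (the rear-most buttock point) is ``PH``.
    """
    cloud.require_nonempty("find_hip_point")
    cy = float(cloud.y.mean())
    band = np.abs(cloud.y - cy) <= config.hip_band_halfwidth
    if not band.any():
        raise LandmarkError(
            "no points in the hip band around the geometric center"
        )
    sub = cloud.points[band]
    ph = sub[np.argmin(sub[:, 2])]
    return (float(ph[0]), float(ph[1]), float(ph[2])), float(ph[1])


def compute_lateral_midline(
    cloud: PointCloud, PH: tuple[float, float, float], thH: float
) -> float:
    """Midpoint of the transversal extremes in a band around the hip plane."""
    cloud.require_nonempty("compute_lateral_midline")
    band = np.abs(cloud.y - PH[1]) < thH
    if not band.any():
        raise LandmarkError("empty band around the hip plane (thH too small?)")
    xs = cloud.x[band]
    return float((xs.min() + xs.max()) / 2.0)


def split_upper_lower(
    cloud: PointCloud, hip_y: float
) -> tuple[PointCloud, PointCloud]:
    """Divide at the hip plane; boundary points (y == hip_y) go to the upper part."""
    lower = cloud.points[cloud.y < hip_y]
    upper = cloud.points[cloud.y >= hip_y]
    return PointCloud(upper), PointCloud(lower)


def estimate_knee_height(
    leg: PointCloud, hip_y: float, config: SegmentationConfig
) -> float:
    """Proportion-based knee height for one leg.

    The knee sits at ``knee_height_frac / hip_height_frac`` of the
    foot-to-hip distance above the foot — the standard adult ratio of knee
    to hip height.
    """
    leg.require_nonempty("estimate_knee_height")
    y0 = float(leg.y.min())
    return y0 + (config.knee_height_frac / config.hip_height_frac) * (hip_y - y0)


def upper_body_contour(
    upper: PointCloud, config: SegmentationConfig
) -> ContourPolyline:
    """Outline of the upper body projected onto the XY plane."""
    upper.require_nonempty("upper_body_contour")
    if len(upper) < config.min_contour_points:
        raise ContourError(
            f"need at least {config.min_contour_points} upper-body points"
        )
    xy = upper.points[:, [0, 1]]
    return ContourPolyline(concave_hull_2d(xy, config.concave_alpha))


# -- arm junctions ----------------------------------------------------------


def _resample_polyline(verts: np.ndarray, step: float) -> np.ndarray:
    """Resample an open polyline at uniform arc-length spacing."""
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= step:
        return verts[[0, -1]]
    targets = np.arange(0.0, total, step)
    x = np.interp(targets, s, verts[:, 0])
    y = np.interp(targets, s, verts[:, 1])
    out = np.c_[x, y]
    return np.vstack([out, verts[-1]])


def _side_arc(vertices: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Longest circularly-contiguous run of contour vertices with mask True."""
    n = len(mask)
    if not mask.any():
        raise LandmarkError("side sub-contour is empty")
    if mask.all():
        return vertices
    # rotate so the sequence starts on a False vertex, then split runs
    start = int(np.argmin(mask))
    rolled = np.roll(mask, -start)
    idx = (np.arange(n) + start) % n
    runs: list[np.ndarray] = []
    cur: list[int] = []
    for k in range(n):
        if rolled[k]:
            cur.append(idx[k])
        elif cur:
            runs.append(np.array(cur))
            cur = []
    if cur:
        runs.append(np.array(cur))
    best = max(runs, key=len)
    return vertices[best]


def _walk_side(
    arc: np.ndarray, side_sign: float, config: SegmentationConfig, side: str
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Find (junction_down, junction_up) on one side's outline arc.

    ``side_sign`` is -1 for the subject's right (arm extends toward -x) and
    +1 for the left. The arc is walked from its low end; the first resampled
    step whose |x|-component exceeds ``thdir`` after the initial bottom-edge
    run marks the armpit. The shoulder-top point is the first later point
    returning to within ``eps_x`` of the armpit's x after traversing the arm.
    """
    if arc.shape[0] < 3:
        raise NoArmFoundError(f"{side}: side arc too short")
    if arc[0, 1] > arc[-1, 1]:
        arc = arc[::-1]
    pts = _resample_polyline(arc, config.contour_step)
    steps = np.diff(pts, axis=0)
    lens = np.linalg.norm(steps, axis=1)
    ok = lens > 1e-12
    xcomp = np.zeros(len(steps))
    xcomp[ok] = np.abs(steps[ok, 0]) / lens[ok]

    i = 0
    while i < len(steps) and xcomp[i] > config.thdir:
        i += 1  # skip the horizontal bottom (hip-cut) edge

    for j in range(i, len(steps)):
        if xcomp[j] <= config.thdir:
            continue
        down = pts[j]
        rest = pts[j + 1:]
        if len(rest) == 0:
            continue
        dx = np.abs(rest[:, 0] - down[0])
        outside = np.nonzero(dx > config.eps_x)[0]
        if len(outside) == 0:
            continue
        k0 = outside[0]
        # direct return: leaves the eps_x neighborhood, then re-enters above
        for k in range(k0, len(rest)):
            if dx[k] <= config.eps_x and rest[k, 1] > down[1]:
                return (float(down[0]), float(down[1])), (
                    float(rest[k, 0]),
                    float(rest[k, 1]),
                )
        # fallback: the outline went out along the arm but never came back
        # within eps_x; take the closest-x point after the hand extreme.
        lateral = side_sign * (rest[:, 0] - down[0])  # >0 beyond the armpit
        if lateral.max() >= config.min_arm_extent:
            hand = int(np.argmax(lateral))
            after = rest[hand:]
            cand = np.nonzero(after[:, 1] > down[1])[0]
            if len(cand):
                dxa = np.abs(after[cand, 0] - down[0])
                best = cand[int(np.argmin(dxa))]
                up = after[best]
                logger.warning(
                    "%s: junction-up not within eps_x=%g of junction-down; "
                    "falling back to closest-x point (|dx|=%g)",
                    side, config.eps_x, float(np.min(dxa)),
                )
                return (float(down[0]), float(down[1])), (
                    float(up[0]),
                    float(up[1]),
                )
    raise NoArmFoundError(
        f"{side}: no outline step exceeds thdir={config.thdir}; "
        "no arm detected on this side"
    )


def find_arm_junctions(
    contour: ContourPolyline, xH: float, config: SegmentationConfig
) -> tuple[
    tuple[float, float],
    tuple[float, float],
    tuple[float, float],
    tuple[float, float],
]:
    """Locate (PRAdown, PRAup, PLAdown, PLAup) on the upper-body outline."""
    verts = contour.vertices
    right_arc = _side_arc(verts, verts[:, 0] < xH)
    left_arc = _side_arc(verts, verts[:, 0] > xH)
    pra_down, pra_up = _walk_side(right_arc, -1.0, config, "right")
    pla_down, pla_up = _walk_side(left_arc, +1.0, config, "left")
    return pra_down, pra_up, pla_down, pla_up


# ---------------------------------------------------------------------------
# Label assignment and orchestration


def assign_segments(
    cloud: PointCloud,
    landmarks: SegmentationLandmarks,
    config: SegmentationConfig,
) -> SegmentedScan:
    """Partition every point into exactly one of the nine segments."""
    pts = cloud.points
    labels = np.empty(len(pts), dtype=np.int8)

    upper = pts[:, 1] >= landmarks.hip_y
    lower = ~upper

    # legs: split left/right at xH (ties to the left), thigh above the knee
    left_leg = lower & (pts[:, 0] >= landmarks.xH)
    right_leg = lower & (pts[:, 0] < landmarks.xH)
    labels[right_leg & (pts[:, 1] > landmarks.knee_y_right)] = BodySegment.RIGHT_THIGH
    labels[right_leg & (pts[:, 1] <= landmarks.knee_y_right)] = BodySegment.RIGHT_LOWER_LEG
    labels[left_leg & (pts[:, 1] > landmarks.knee_y_left)] = BodySegment.LEFT_THIGH
    labels[left_leg & (pts[:, 1] <= landmarks.knee_y_left)] = BodySegment.LEFT_LOWER_LEG

    # arms: everything lateral of the armpit x (ties go to the torso)
    right_arm = upper & (pts[:, 0] < landmarks.PRAdown[0])
    left_arm = upper & (pts[:, 0] > landmarks.PLAdown[0])
    labels[right_arm] = BodySegment.RIGHT_ARM
    labels[left_arm] = BodySegment.LEFT_ARM

    middle = upper & ~right_arm & ~left_arm
    head = middle & (pts[:, 1] > landmarks.shoulder_y)
    labels[head] = BodySegment.HEAD
    torso = middle & ~head
    labels[torso & (pts[:, 1] >= landmarks.torso_split_y)] = BodySegment.UPPER_TORSO
    labels[torso & (pts[:, 1] < landmarks.torso_split_y)] = BodySegment.LOWER_TORSO

    return SegmentedScan(cloud=cloud, labels=labels, landmarks=landmarks)


def segment_body(
    cloud: PointCloud, config: SegmentationConfig | None = None
) -> SegmentedScan:
    """Run the full segmentation pipeline on a canonical T-pose cloud."""
    cfg = config if config is not None else SegmentationConfig()
    cloud.require_nonempty("segment_body")

    def stage(name: str, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            exc.add_note(f"segmentation stage: {name}")
            raise

    PH, hip_y = stage("find_hip_point", find_hip_point, cloud, cfg)
    xH = stage("compute_lateral_midline", compute_lateral_midline, cloud, PH, cfg.thH)
    upper, lower = stage("split_upper_lower", split_upper_lower, cloud, hip_y)

    right_leg = PointCloud(lower.points[lower.x < xH]) if len(lower) else lower
    left_leg = PointCloud(lower.points[lower.x >= xH]) if len(lower) else lower
    knee_r = stage("estimate_knee_height", estimate_knee_height, right_leg, hip_y, cfg)
    knee_l = stage("estimate_knee_height", estimate_knee_height, left_leg, hip_y, cfg)

    contour = stage("upper_body_contour", upper_body_contour, upper, cfg)
    pra_down, pra_up, pla_down, pla_up = stage(
        "find_arm_junctions", find_arm_junctions, contour, xH, cfg
    )

    shoulder_y = max(pra_up[1], pla_up[1])
    torso_mask = (
        (upper.x >= pra_down[0]) & (upper.x <= pla_down[0]) & (upper.y <= shoulder_y)
    )
    torso_y = upper.y[torso_mask]
    if torso_y.size == 0:
        raise LandmarkError("no torso points between the arm junctions")
    torso_split_y = float((torso_y.min() + torso_y.max()) / 2.0)

    landmarks = SegmentationLandmarks(
        PH=PH,
        xH=xH,
        hip_y=hip_y,
        knee_y_right=knee_r,
        knee_y_left=knee_l,
        PRAdown=pra_down,
        PRAup=pra_up,
        PLAdown=pla_down,
        PLAup=pla_up,
        shoulder_y=shoulder_y,
        torso_split_y=torso_split_y,
    )
    return stage("assign_segments", assign_segments, cloud, landmarks, cfg)


# ---------------------------------------------------------------------------
# Output


def write_segmented_scan(scan: SegmentedScan, path: str) -> None:
    """Write an ascii PLY with an integer ``label`` vertex property (0-8)."""
    n = len(scan.cloud)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {n}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property uchar label\nend_header\n")
        for (x, y, z), lab in zip(scan.cloud.points, scan.labels):
            fh.write(f"{x:.9g} {y:.9g} {z:.9g} {int(lab)}\n")


def write_landmarks(landmarks: SegmentationLandmarks, path: str) -> None:
    """Write landmarks as a flat ``key: value`` text sidecar (meters)."""
    lm = landmarks
    rows = {
        "PH.x": lm.PH[0], "PH.y": lm.PH[1], "PH.z": lm.PH[2],
        "xH": lm.xH, "hip_y": lm.hip_y,
        "knee_y_right": lm.knee_y_right, "knee_y_left": lm.knee_y_left,
        "PRAdown.x": lm.PRAdown[0], "PRAdown.y": lm.PRAdown[1],
        "PRAup.x": lm.PRAup[0], "PRAup.y": lm.PRAup[1],
        "PLAdown.x": lm.PLAdown[0], "PLAdown.y": lm.PLAdown[1],
        "PLAup.x": lm.PLAup[0], "PLAup.y": lm.PLAup[1],
        "shoulder_y": lm.shoulder_y, "torso_split_y": lm.torso_split_y,
    }
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in rows.items():
            fh.write(f"{key}: {val:.6f}\n")
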