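"""Segmentation landmarks, contour extraction and the 9-part partition."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from anthroscan import (
    BodySegment,
    BodyShapeParams,
    PointCloud,
    SegmentationConfig,
    generate_body,
    segment_body,
)
from anthroscan.errors import (
    ContourError,
    EmptyCloudError,
    LandmarkError,
    NoArmFoundError,
    ValidationError,
)
from anthroscan.segmentation import (
    ContourPolyline,
    assign_segments,
    compute_lateral_midline,
    concave_hull_2d,
    estimate_knee_height,
    find_arm_junctions,
    find_hip_point,
    split_upper_lower,
    upper_body_contour,
    write_landmarks,
    write_segmented_scan,
)

from conftest import cylinder_cloud

RIGHT = {BodySegment.RIGHT_ARM, BodySegment.RIGHT_THIGH, BodySegment.RIGHT_LOWER_LEG}
SWAP = {
    BodySegment.RIGHT_ARM: BodySegment.LEFT_ARM,
    BodySegment.LEFT_ARM: BodySegment.RIGHT_ARM,
    BodySegment.RIGHT_THIGH: BodySegment.LEFT_THIGH,
    BodySegment.LEFT_THIGH: BodySegment.RIGHT_THIGH,
    BodySegment.RIGHT_LOWER_LEG: BodySegment.LEFT_LOWER_LEG,
    BodySegment.LEFT_LOWER_LEG: BodySegment.RIGHT_LOWER_LEG,
    BodySegment.HEAD: BodySegment.HEAD,
    BodySegment.UPPER_TORSO: BodySegment.UPPER_TORSO,
    BodySegment.LOWER_TORSO: BodySegment.LOWER_TORSO,
}


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValidationError):
            SegmentationConfig(thdir=1.5)
        with pytest.raises(ValidationError):
            SegmentationConfig(thH=-0.01)

    def test_file_round_trip(self, tmp_path):
        cfg = SegmentationConfig(thH=0.03, thdir=0.4)
        path = str(tmp_path / "cfg.txt")
        cfg.to_file(path)
        assert SegmentationConfig.from_file(path) == cfg

    def test_unknown_key_errors(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("no_such_threshold: 1\n")
        with pytest.raises(ValidationError):
            SegmentationConfig.from_file(str(p))

    def test_scaled_scales_lengths_only(self):
        cfg = SegmentationConfig().scaled(2.0)
        assert cfg.thH == pytest.approx(0.04)
        assert cfg.thdir == 0.5
        assert cfg.knee_height_frac == 0.285


class TestHipPoint:
    def test_unique_argmin(self):
        pts = [[0.0, 0.9, 0.1], [0.01, 0.95, -0.12], [0.0, 1.0, 0.0]]
        ph, hip_y = find_hip_point(PointCloud(pts), SegmentationConfig(
            hip_band_halfwidth=0.5))
        assert ph == (0.01, 0.95, -0.12)
        assert hip_y == 0.95

    def test_synthetic_hip_height(self, small_body, default_config):
        cloud, _, params = small_body
        _, hip_y = find_hip_point(cloud, default_config)
        assert abs(hip_y - params.hip_height_frac * params.stature) \
            <= default_config.hip_band_halfwidth

    def test_empty_centroid_band_errors(self):
        # two blobs far apart: the centroid falls in the gap between them
        blob = cylinder_cloud(height=0.1, n=500).points
        pts = np.vstack([blob, blob + np.array([0.0, 2.0, 0.0])])
        with pytest.raises(LandmarkError):
            find_hip_point(PointCloud(pts), SegmentationConfig())


class TestLateralMidline:
    def test_midpoint_of_extremes(self):
        pts = [[-0.18, 1.0, 0.0], [0.14, 1.0, 0.0], [0.0, 1.0, 0.1]]
        xh = compute_lateral_midline(PointCloud(pts), (0.0, 1.0, 0.0), 0.05)
        assert xh == pytest.approx(-0.02)

    def test_symmetric_body_gives_zero(self, small_body, default_config):
        cloud, _, _ = small_body
        ph, _ = find_hip_point(cloud, default_config)
        xh = compute_lateral_midline(cloud, ph, default_config.thH)
        assert abs(xh) < 0.01

    def test_translation_equivariance(self, small_body, default_config):
        cloud, _, _ = small_body
        ph, _ = find_hip_point(cloud, default_config)
        xh = compute_lateral_midline(cloud, ph, default_config.thH)
        moved = cloud.translated([0.5, 0.0, 0.0])
        ph2 = (ph[0] + 0.5, ph[1], ph[2])
        xh2 = compute_lateral_midline(moved, ph2, default_config.thH)
        assert xh2 == pytest.approx(xh + 0.5, abs=1e-9)

    def test_empty_band_errors(self):
        pc = cylinder_cloud(n=100)
        with pytest.raises(LandmarkError):
            compute_lateral_midline(pc, (0.0, 50.0, 0.0), 0.01)


class TestSplitUpperLower:
    def test_counts_conserved(self):
        pc = cylinder_cloud(n=2000)
        upper, lower = split_upper_lower(pc, 0.5)
        assert len(upper) + len(lower) == len(pc)
        assert (upper.y >= 0.5).all() and (lower.y < 0.5).all()

    def test_hip_below_everything(self):
        pc = cylinder_cloud(n=100)
        upper, lower = split_upper_lower(pc, -1.0)
        assert len(lower) == 0 and len(upper) == len(pc)


class TestKneeHeight:
    def test_formula(self):
        leg = PointCloud([[0.0, 0.0, 0.0], [0.0, 0.95, 0.0]])
        cfg = SegmentationConfig()
        knee = estimate_knee_height(leg, 0.95, cfg)
        assert knee == pytest.approx(0.95 * 0.285 / 0.53)

    def test_scale_equivariance(self):
        leg = PointCloud([[0.0, 0.1, 0.0], [0.0, 1.0, 0.0]])
        cfg = SegmentationConfig()
        k1 = estimate_knee_height(leg, 0.9, cfg)
        k2 = estimate_knee_height(leg.scaled(2.0), 1.8, cfg)
        assert k2 == pytest.approx(2 * k1)

    def test_empty_leg_errors(self):
        with pytest.raises(EmptyCloudError):
            estimate_knee_height(
                PointCloud(np.empty((0, 3))), 1.0, SegmentationConfig()
            )


def _fill_polygon(poly: Polygon, spacing: float, seed: int = 0) -> np.ndarray:
    import shapely

    minx, miny, maxx, maxy = poly.bounds
    rng = np.random.default_rng(seed)
    n = int((maxx - minx) * (maxy - miny) / spacing**2 * 2.0)
    pts = rng.uniform([minx, miny], [maxx, maxy], (n, 2))
    keep = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
    return pts[keep]


class TestConcaveHull:
    def test_rectangle_matches_convex_outline(self):
        poly = Polygon([(0, 0), (0.4, 0), (0.4, 0.2), (0, 0.2)])
        pts = _fill_polygon(poly, 0.005)
        hull = concave_hull_2d(pts, alpha=0.05)
        out = Polygon(hull)
        assert out.area == pytest.approx(poly.area, rel=0.05)
        assert out.length == pytest.approx(poly.length, rel=0.05)

    def test_t_shape_captures_reentrant_corners(self):
        # a T: vertical bar 0.2 wide, crossbar 0.6 wide on top
        poly = Polygon([
            (-0.1, 0.0), (0.1, 0.0), (0.1, 0.4), (0.3, 0.4), (0.3, 0.55),
            (-0.3, 0.55), (-0.3, 0.4), (-0.1, 0.4),
        ])
        pts = _fill_polygon(poly, 0.004, seed=1)
        hull_pts = concave_hull_2d(pts, alpha=0.04)
        out = Polygon(hull_pts)
        inter = out.intersection(poly).area
        union = out.union(poly).area
        assert inter / union > 0.95  # matches the true outline...
        from shapely.geometry import MultiPoint

        convex_area = MultiPoint(pts.tolist()).convex_hull.area
        assert out.area < 0.85 * convex_area  # ...and is genuinely concave

    def test_too_few_points_errors(self):
        with pytest.raises(ContourError):
            concave_hull_2d(np.array([[0, 0], [1, 0], [0, 1]]), alpha=1.0)

    def test_collinear_errors(self):
        pts = np.c_[np.linspace(0, 1, 50), np.zeros(50)]
        with pytest.raises(ContourError):
            concave_hull_2d(pts, alpha=0.5)


class TestArmJunctions:
    def test_junctions_near_constructed_armpits(self, small_scan, small_body):
        _, _, params = small_body
        lm = small_scan.landmarks
        flank_x = 0.167  # torso half-width at shoulder height (construction)
        armpit_y = params.shoulder_height_frac * params.stature \
            - params.upper_arm[0]
        assert lm.PRAdown[0] == pytest.approx(-flank_x, abs=0.03)
        assert lm.PRAdown[1] == pytest.approx(armpit_y, abs=0.03)
        assert lm.PLAdown[0] == pytest.approx(flank_x, abs=0.03)
        assert lm.PRAup[1] > lm.PRAdown[1]
        assert lm.PLAup[1] > lm.PLAdown[1]
        assert abs(lm.PRAup[0] - lm.PRAdown[0]) <= 2 * SegmentationConfig().eps_x

    def test_armless_cylinder_raises(self, default_config):
        pc = cylinder_cloud(radius=0.15, height=0.8, n=30_000, seed=9)
        contour = upper_body_contour(pc, default_config)
        with pytest.raises(NoArmFoundError):
            find_arm_junctions(contour, 0.0, default_config)

    def test_mirrored_contour_swaps_sides(self, small_scan, small_body,
                                          default_config):
        cloud, _, _ = small_body
        lm = small_scan.landmarks
        upper = PointCloud(cloud.points[cloud.y >= lm.hip_y])
        contour = upper_body_contour(upper, default_config)
        mirrored = ContourPolyline(
            np.c_[2 * lm.xH - contour.vertices[:, 0], contour.vertices[:, 1]]
        )
        pra_d, pra_u, pla_d, pla_u = find_arm_junctions(
            contour, lm.xH, default_config
        )
        mra_d, mra_u, mla_d, mla_u = find_arm_junctions(
            mirrored, lm.xH, default_config
        )
        assert mra_d[0] == pytest.approx(2 * lm.xH - pla_d[0], abs=1e-9)
        assert mra_d[1] == pytest.approx(pla_d[1], abs=1e-9)
        assert mla_u[0] == pytest.approx(2 * lm.xH - pra_u[0], abs=1e-9)
        assert mla_u[1] == pytest.approx(pra_u[1], abs=1e-9)


class TestAssignAndOrchestrate:
    def test_partition_total(self, small_scan):
        counts = small_scan.counts()
        assert sum(counts.values()) == len(small_scan.cloud)

    def test_all_nine_segments_nonempty(self, small_scan):
        assert all(v > 0 for v in small_scan.counts().values())

    def test_arm_points_labeled_as_arms(self, default_config):
        # provenance oracle: regenerate the arm primitives and check labels
        params = BodyShapeParams(density=15_000, seed=1)
        cloud, _ = generate_body(params)
        scan = segment_body(cloud, default_config)
        span_frac = np.abs(cloud.x) > 0.25  # well past the torso flank
        at_shoulder = np.abs(
            cloud.y - params.shoulder_height_frac * params.stature
        ) < 1.5 * params.upper_arm[0]
        arm_points = span_frac & at_shoulder
        labels = scan.labels[arm_points]
        arm_share = np.isin(
            labels, [BodySegment.RIGHT_ARM, BodySegment.LEFT_ARM]
        ).mean()
        assert arm_share >= 0.99

    def test_determinism(self, small_body, default_config):
        cloud, _, _ = small_body
        s1 = segment_body(cloud, default_config)
        s2 = segment_body(cloud, default_config)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_empty_cloud_errors(self, default_config):
        with pytest.raises(EmptyCloudError):
            segment_body(PointCloud(np.empty((0, 3))), default_config)

    def test_mirror_symmetry_swaps_labels(self, small_body, default_config):
        cloud, _, _ = small_body
        scan = segment_body(cloud, default_config)
        mirrored = PointCloud(cloud.points * np.array([-1.0, 1.0, 1.0]))
        mscan = segment_body(mirrored, default_config)
        swapped = np.array([SWAP[BodySegment(v)] for v in scan.labels])
        agreement = (mscan.labels == swapped).mean()
        assert agreement > 0.99  # boundary-tie points may differ

    def test_scale_equivariance_of_landmarks(self, small_body, default_config):
        cloud, _, _ = small_body
        s = 2.0
        lm1 = segment_body(cloud, default_config).landmarks
        lm2 = segment_body(cloud.scaled(s), default_config.scaled(s)).landmarks
        assert lm2.hip_y == pytest.approx(s * lm1.hip_y, abs=0.02)
        assert lm2.xH == pytest.approx(s * lm1.xH, abs=0.02)
        assert lm2.knee_y_right == pytest.approx(s * lm1.knee_y_right, abs=0.02)
        assert lm2.PRAdown[0] == pytest.approx(s * lm1.PRAdown[0], abs=0.04)
        assert lm2.PRAdown[1] == pytest.approx(s * lm1.PRAdown[1], abs=0.04)
        assert lm2.shoulder_y == pytest.approx(s * lm1.shoulder_y, abs=0.04)

    def test_landmark_invariants(self, small_scan):
        lm = small_scan.landmarks
        assert lm.hip_y == lm.PH[1]
        assert lm.PRAdown[0] < lm.xH < lm.PLAdown[0]
        assert lm.PRAdown[1] < lm.PRAup[1]

    def test_sidecar_outputs(self, small_scan, tmp_path):
        ply = tmp_path / "seg.ply"
        lmtxt = tmp_path / "lm.txt"
        write_segmented_scan(small_scan, str(ply))
        write_landmarks(small_scan.landmarks, str(lmtxt))
        header = ply.read_text().splitlines()[:8]
        assert any("property uchar label" in line for line in header)
        assert "hip_y" in lmtxt.read_text()
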