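"""Pinhole projection, extrinsic calibration, triangulation, grid verification."""

import numpy as np
import pytest

from surftrack.camera import (
    CalibrationError,
    Camera,
    CameraIntrinsics,
    CameraPose,
    DegenerateGeometryError,
    GridPlate,
    calibrate_extrinsics,
    project,
    select_camera_pair,
    triangulate_pair,
    triangulate_points,
    undistort_pixels,
    verify_grid,
)
from surftrack.geometry import RigidTransform
from surftrack.simulate import SceneConfig, grid_fixture, make_rig
from surftrack.pipeline import calibrate_rig


def simple_camera(**intr_kw) -> tuple[CameraIntrinsics, CameraPose]:
    intr = CameraIntrinsics(fx=1000.0, fy=1000.0, cx=500.0, cy=400.0,
                            width=1000, height=800, **intr_kw)
    return intr, CameraPose(RigidTransform.identity(), "test")


class TestProjection:
    def test_point_on_optical_axis_hits_principal_point(self):
        intr, pose = simple_camera()
        np.testing.assert_allclose(project(intr, pose, [0, 0, 1000.0]), (500, 400))

    def test_closed_form_off_axis(self):
        intr, pose = simple_camera()
        px = project(intr, pose, [100.0, 0.0, 2000.0])
        np.testing.assert_allclose(px, (500 + 1000 * 100 / 2000, 400), atol=1e-12)

    def test_negative_k1_shrinks_radial_displacement(self):
        """Barrel distortion pulls off-axis points toward the principal point,
        matching a direct evaluation of the distortion polynomial."""
        intr0, pose = simple_camera()
        intr1, _ = simple_camera(k1=-0.1)
        p = np.array([150.0, 120.0, 1000.0])
        r0 = np.linalg.norm(project(intr0, pose, p) - (500, 400))
        r1 = np.linalg.norm(project(intr1, pose, p) - (500, 400))
        assert r1 < r0
        x, y = 0.15, 0.12
        r2 = x * x + y * y
        expected_u = 500 + 1000 * x * (1 - 0.1 * r2)
        assert project(intr1, pose, p)[0] == pytest.approx(expected_u, abs=1e-9)

    def test_point_behind_camera_raises(self):
        intr, pose = simple_camera()
        with pytest.raises(ValueError):
            project(intr, pose, [0.0, 0.0, -10.0])

    def test_undistort_inverts_distortion(self):
        intr, pose = simple_camera(k1=-0.08, k2=0.01, p1=1e-4, p2=-2e-4)
        pts = np.array([[50.0, -30.0, 900.0], [200.0, 150.0, 1500.0]])
        px = project(intr, pose, pts)
        xy = undistort_pixels(intr, px)
        np.testing.assert_allclose(xy, pts[:, :2] / pts[:, 2:3], atol=1e-12)


class TestTriangulation:
    def test_noiseless_recovery(self, rig, rng):
        """triangulate(project(p)) recovers p to machine precision."""
        cams = list(rig.values())
        pts = rng.uniform([-150, 50, 950], [150, 250, 1250], (50, 3))
        a = (cams[0].intrinsics, cams[0].pose)
        b = (cams[1].intrinsics, cams[1].pose)
        px_a = project(*a, pts)
        px_b = project(*b, pts)
        rec, res = triangulate_points(a, b, px_a, px_b)
        assert np.max(np.linalg.norm(rec - pts, axis=1) / np.linalg.norm(pts, axis=1)) < 1e-9
        assert np.max(res) < 1e-8

    def test_montecarlo_submillimetre_at_90_degrees(self, rng):
        """0.5-px noise on two cameras 90 degrees apart at 1.5 m: median 3D
        error stays sub-millimetre."""
        intr = CameraIntrinsics.from_lens()
        rot_a = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        pose_a = CameraPose(RigidTransform(rot_a, -rot_a @ np.array([0, -1500.0, 0])), "a")
        rot_b = np.array([[0, -1.0, 0], [0, 0, -1.0], [1.0, 0, 0]])
        pose_b = CameraPose(RigidTransform(rot_b, -rot_b @ np.array([-1500.0, 0, 0])), "b")
        pts = rng.uniform(-100, 100, (1000, 3))
        px_a = project(intr, pose_a, pts) + rng.normal(0, 0.5, (1000, 2))
        px_b = project(intr, pose_b, pts) + rng.normal(0, 0.5, (1000, 2))
        rec, _ = triangulate_points((intr, pose_a), (intr, pose_b), px_a, px_b)
        err = np.linalg.norm(rec - pts, axis=1)
        assert np.median(err) < 1.0
        assert np.percentile(err, 95) < 1.0

    def test_identical_poses_degenerate(self):
        cam = simple_camera()
        with pytest.raises(DegenerateGeometryError):
            triangulate_pair(cam, cam, (500.0, 400.0), (510.0, 400.0))


class TestCalibration:
    def test_noiseless_recovery_and_init_robustness(self, scene_cfg, rig):
        fixture = grid_fixture(scene_cfg, noise_px=0.0)
        cam = rig["front"]
        obj, img = fixture.calib_observations("front")
        # perturbed init: 5 deg / 50 mm off the truth
        perturb = RigidTransform.from_rotvec((3.0, -2.0, 3.0), (30.0, -20.0, 30.0))
        init = CameraPose(perturb.compose(cam.pose.transform), "front")
        pose, rms = calibrate_extrinsics(cam.intrinsics, obj, img, init)
        assert rms < 1e-8
        assert np.linalg.norm(pose.transform.translation - cam.pose.transform.translation) < 1e-6
        rot_err_deg = np.rad2deg(np.arccos(np.clip(
            (np.trace(pose.transform.rotation.T @ cam.pose.transform.rotation) - 1) / 2, -1, 1)))
        assert rot_err_deg < 1e-7

    def test_identity_init_immediate_convergence(self, scene_cfg, rig):
        fixture = grid_fixture(scene_cfg, noise_px=0.0)
        cam = rig["left"]
        obj, img = fixture.calib_observations("left")
        pose, rms = calibrate_extrinsics(cam.intrinsics, obj, img, cam.pose)
        assert rms < 1e-8
        assert pose.transform.is_close(cam.pose.transform, atol=1e-8)

    def test_noise_floor_equals_injected_noise(self, scene_cfg):
        """RMS reprojection at the optimum matches the 0.5-px injected noise."""
        fixture = grid_fixture(scene_cfg, noise_px=0.5)
        _, rms = calibrate_rig(fixture)
        for v in rms.values():
            assert v == pytest.approx(0.5, rel=0.10)

    def test_insufficient_or_collinear_observations_error(self, rig):
        cam = rig["front"]
        obj = np.array([[0, 0, 1000.0], [10, 0, 1000.0], [20, 0, 1000.0],
                        [30, 0, 1000.0], [40, 0, 1000.0]])
        img = np.zeros((5, 2)) + (2748, 1836)
        with pytest.raises(CalibrationError):
            calibrate_extrinsics(cam.intrinsics, obj, img, cam.pose)
        obj6 = np.vstack([obj, [[50, 0, 1000.0]]])  # collinear
        img6 = np.zeros((6, 2)) + (2748, 1836)
        with pytest.raises(CalibrationError):
            calibrate_extrinsics(cam.intrinsics, obj6, img6, cam.pose)


class TestPairSelection:
    def test_side_rules(self):
        all_ok = {"front": True, "left": True, "right": True}
        assert select_camera_pair("left", all_ok) == ("front", "left")
        assert select_camera_pair("right", all_ok) == ("front", "right")
        assert select_camera_pair("right", {"front": False, "left": True, "right": True}) \
            == ("left", "right")

    def test_single_camera_flags_invalid(self):
        assert select_camera_pair("left", {"front": True, "left": False, "right": False}) is None

    def test_unknown_side_rejected(self):
        with pytest.raises(ValueError):
            select_camera_pair("up", {})


class TestGridVerification:
    def test_grid_plate_point_count_and_spacing(self):
        plate = GridPlate(RigidTransform.identity())
        pts = plate.local_points()
        assert pts.shape == (2378, 3)
        # neighbouring columns are 5 mm apart
        assert np.linalg.norm(pts[1] - pts[0]) == pytest.approx(5.0)

    def test_three_four_five_triangle(self):
        err = np.array([0.3, 0.0, 0.4])
        assert np.linalg.norm(err) == pytest.approx(0.5)

    def test_noiseless_detections_give_zero_error(self, scene_cfg):
        fixture = grid_fixture(scene_cfg, noise_px=0.0)
        report = verify_grid(fixture.rig, fixture.verify_plate, fixture.verify_detections())
        for axes in report.per_pair.values():
            for mean, _, p95 in axes.values():
                assert mean < 1e-9
                assert p95 < 1e-9

    def test_report_matches_bruteforce_reaggregation(self, scene_cfg):
        """Statistics in the report equal an independent recomputation from
        raw per-point errors."""
        fixture = grid_fixture(scene_cfg, noise_px=0.5)
        report = verify_grid(fixture.rig, fixture.verify_plate, fixture.verify_detections())
        det = fixture.verify_detections()
        truth = fixture.verify_plate.point_index()
        truth[["x", "y", "z"]] = fixture.verify_plate.world_points()
        pair = ("front", "left")
        da = det[det["camera"] == "front"]
        db = det[det["camera"] == "left"]
        m = da.merge(db, on=["row", "col"], suffixes=("_a", "_b")).merge(truth, on=["row", "col"])
        rig_pair = (
            (fixture.rig["front"].intrinsics, fixture.rig["front"].pose),
            (fixture.rig["left"].intrinsics, fixture.rig["left"].pose),
        )
        pts, _ = triangulate_points(
            *rig_pair,
            m[["u_px_a", "v_px_a"]].to_numpy(), m[["u_px_b", "v_px_b"]].to_numpy(),
        )
        err = np.abs(pts - m[["x", "y", "z"]].to_numpy())
        for i, axis in enumerate(("lr", "ap", "si")):
            mean, sd, p95 = report.per_pair[pair][axis]
            assert mean == pytest.approx(err[:, i].mean(), abs=1e-12)
            assert sd == pytest.approx(err[:, i].std(ddof=1), abs=1e-12)
            # declared percentile rule: linear interpolation between order stats
            srt = np.sort(err[:, i])
            q = 0.95 * (len(srt) - 1)
            lo, hi = int(np.floor(q)), int(np.ceil(q))
            expected_p95 = srt[lo] + (q - lo) * (srt[hi] - srt[lo])
            assert p95 == pytest.approx(expected_p95, abs=1e-12)

    def test_3d_mean_at_least_each_axis_mean(self, scene_cfg):
        fixture = grid_fixture(scene_cfg, noise_px=0.5)
        report = verify_grid(fixture.rig, fixture.verify_plate, fixture.verify_detections())
        for axes in report.per_pair.values():
            for axis in ("lr", "ap", "si"):
                assert axes["3d"][0] >= axes[axis][0]
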