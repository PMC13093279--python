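"""Kabsch/ICP registration, respiratory smoothing, origin rule, tracking."""

import numpy as np
import pytest

from surftrack.geometry import Displacement6D, RigidTransform, from_displacement
from surftrack.registration import (
    ICPConfig,
    LabeledCloud,
    RegistrationError,
    TrackConfig,
    icp,
    kabsch,
    set_origin,
    smooth_series,
    track_sequence,
)
from surftrack.simulate import MotionModel, SceneConfig, make_layout, simulate_intrafraction

ORIGIN = np.array([0.0, 150.0, 1100.0])


def rigid(rng, max_trans=5.0, max_rot=1.0) -> RigidTransform:
    return from_displacement(
        Displacement6D(*rng.uniform(-max_trans, max_trans, 3),
                       *rng.uniform(-max_rot, max_rot, 3)),
        ORIGIN,
    )


class TestKabsch:
    def test_identity_for_equal_clouds(self, rng):
        pts = rng.uniform(-100, 100, (8, 3))
        assert kabsch(pts, pts).is_close(RigidTransform.identity(), atol=1e-12)

    def test_exact_recovery_of_constructed_transform(self, rng):
        pts = rng.uniform(-100, 100, (10, 3))
        truth = RigidTransform.from_rotvec((0, 0, 10.0), (1.0, 2.0, 3.0))
        rec = kabsch(pts, truth.apply(pts))
        assert rec.is_close(truth, atol=1e-9)

    def test_residual_equals_bruteforce_rmsd(self, rng):
        src = rng.uniform(-50, 50, (12, 3))
        tgt = rigid(rng).apply(src) + rng.normal(0, 0.3, (12, 3))
        t = kabsch(src, tgt)
        rmsd = np.sqrt(np.mean(np.sum((t.apply(src) - tgt) ** 2, axis=1)))
        # the optimum cannot be beaten by small perturbations of itself
        for _ in range(20):
            pert = from_displacement(
                Displacement6D(*rng.normal(0, 0.1, 3), *rng.normal(0, 0.05, 3)),
                np.zeros(3),
            )
            worse = np.sqrt(np.mean(np.sum((pert.compose(t).apply(src) - tgt) ** 2, axis=1)))
            assert worse >= rmsd - 1e-12

    def test_collinear_points_rejected(self):
        src = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0.0]])
        with pytest.raises(RegistrationError):
            kabsch(src, src + 1.0)


class TestICP:
    def test_identical_clouds_identity_in_one_iteration(self, abdominal_layout):
        res = icp(abdominal_layout, abdominal_layout)
        assert res.transform.is_close(RigidTransform.identity(), atol=1e-12)
        assert res.iterations == 1

    def test_nearest_equals_labeled_oracle(self, abdominal_layout, rng):
        """For motions far smaller than the marker spacing, nearest-neighbour
        ICP equals the labeled Kabsch fit exactly."""
        for _ in range(200):
            truth = rigid(rng)
            target = abdominal_layout.with_points(truth.apply(abdominal_layout.points))
            nearest = icp(abdominal_layout, target, ICPConfig(correspondence="nearest"))
            labeled = icp(abdominal_layout, target, ICPConfig(correspondence="labeled"))
            assert np.abs(nearest.transform.rotation - labeled.transform.rotation).max() < 1e-9
            assert np.abs(nearest.transform.translation - labeled.transform.translation).max() < 1e-9
            assert nearest.transform.is_close(truth, atol=1e-9)

    def test_rms_non_increasing(self, abdominal_layout, rng):
        truth = rigid(rng)
        noisy = truth.apply(abdominal_layout.points) + rng.normal(0, 0.2, (26, 3))
        res = icp(abdominal_layout, abdominal_layout.with_points(noisy))
        assert all(np.diff(res.rms_history) <= 1e-12)

    def test_dropout_robustness(self, abdominal_layout, rng):
        """4% random marker dropout perturbs the recovered transform by
        < 0.1 mm for 5-mm motions."""
        truth = from_displacement(Displacement6D(5.0, -3.0, 4.0, 0.5, -0.3, 0.4), ORIGIN)
        valid = rng.random(26) >= 0.04
        target = abdominal_layout.with_points(truth.apply(abdominal_layout.points), valid=valid)
        res = icp(abdominal_layout, target)
        assert np.linalg.norm(res.transform.translation - truth.translation) < 0.1

    def test_too_few_markers_flagged(self, abdominal_layout):
        valid = np.zeros(26, bool)
        valid[:2] = True
        target = abdominal_layout.with_points(abdominal_layout.points, valid=valid)
        with pytest.raises(RegistrationError):
            icp(abdominal_layout, target)

    def test_leave_one_out_stability(self, hn_layout):
        """Dropping any single rigid marker changes the recovered transform
        by < 0.2 mm / 0.1 deg for clinical-scale motion, zero noise."""
        truth = from_displacement(Displacement6D(3.0, -5.0, 2.0, 1.0, -0.5, 0.8), ORIGIN)
        target = hn_layout.with_points(truth.apply(hn_layout.points))
        base = icp(hn_layout, target, roles="body_rigid").transform
        rigid_idx = np.nonzero(hn_layout.role_mask("body_rigid"))[0]
        for drop in rigid_idx:
            valid = hn_layout.valid.copy()
            valid[drop] = False
            res = icp(hn_layout, target.with_points(target.points, valid=valid),
                      roles="body_rigid")
            assert np.linalg.norm(res.transform.translation - base.translation) < 0.2
            ang = np.rad2deg(np.arccos(np.clip(
                (np.trace(res.transform.rotation.T @ base.rotation) - 1) / 2, -1, 1)))
            assert ang < 0.1


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full((20, 3), 7.0)
        np.testing.assert_allclose(smooth_series(x), x)

    def test_interior_mean(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])[:, None]
        assert smooth_series(x)[2, 0] == pytest.approx(3.0)

    def test_sinusoid_attenuated_by_moving_average_gain(self):
        """A breathing sinusoid aliased by the 5-s cadence is attenuated by
        the closed-form moving-average gain |sin(5 w dt/2) / (5 sin(w dt/2))|."""
        period, dt, window = 4.0, 5.0, 5
        t = np.arange(0, 1200, dt)
        w = 2 * np.pi / period
        x = np.sin(w * t)[:, None]
        sm = smooth_series(x, window)[:, 0]
        gain = abs(np.sin(window * w * dt / 2) / (window * np.sin(w * dt / 2)))
        interior = slice(2, -2)
        assert np.max(np.abs(sm[interior])) == pytest.approx(gain, rel=0.05)

    def test_trailing_mode_uses_past_frames_only(self):
        x = np.arange(10.0)[:, None]
        sm = smooth_series(x, 5, mode="trailing")
        assert sm[4, 0] == pytest.approx(np.mean([0, 1, 2, 3, 4]))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            smooth_series(np.empty((0, 3)))


class TestOrigin:
    def test_anchor_si_on_rotation_axis(self, abdominal_layout):
        origin = set_origin(abdominal_layout, "abdominal")
        assert origin[0] == 0.0
        assert origin[1] == 150.0
        assert origin[2] == abdominal_layout.get("A2")[2]

    def test_origins_differ_only_in_si(self, hn_layout):
        o = set_origin(hn_layout, "hn")
        moved = hn_layout.points.copy()
        moved[hn_layout.index("H1"), 2] += 50.0
        o2 = set_origin(hn_layout.with_points(moved), "hn")
        np.testing.assert_allclose(o2 - o, [0.0, 0.0, 50.0])

    def test_invalid_anchor_raises(self, abdominal_layout):
        valid = abdominal_layout.valid.copy()
        valid[abdominal_layout.index("A2")] = False
        with pytest.raises(RegistrationError):
            set_origin(abdominal_layout.with_points(abdominal_layout.points, valid=valid),
                       "abdominal")


class TestTracking:
    def test_static_frames_give_identity(self, hn_layout):
        frames = [hn_layout.with_points(hn_layout.points, time_s=5.0 * t) for t in range(10)]
        result = track_sequence(frames, TrackConfig(setup_type="hn"))
        for t in (0, 5, 9):
            assert result.body[t].is_close(RigidTransform.identity(), atol=1e-9)
            assert result.mask[t].is_close(RigidTransform.identity(), atol=1e-9)
        assert not result.unregistered.any()

    def test_rigid_drift_recovered_exactly_from_clouds(self):
        """Zero-noise simulated drift: per-frame transforms match ground
        truth to 1e-6 mm / deg."""
        motion = MotionModel(resp_amplitude_mm=(0, 0, 0), thigh_amplitude_mm=0.0)
        cfg = SceneConfig(layout="hn", pixel_noise_px=0.0, dropout=0.0,
                          duration_s=100.0, seed=4, motion=motion)
        rec = simulate_intrafraction(cfg, with_detections=False)
        result = track_sequence(rec.clouds, TrackConfig(setup_type="hn"))
        for t, truth in enumerate(rec.body_transforms):
            assert np.abs(result.body[t].translation - truth.translation).max() < 1e-6
            assert np.abs(result.body[t].rotation - truth.rotation).max() < 1e-8
        for t, truth in enumerate(rec.mask_transforms):
            assert np.abs(result.mask[t].translation - truth.translation).max() < 1e-6

    def test_respiration_only_suppressed_by_smoothing(self):
        """With respiration but no drift, the recovered body transform equals
        the smoothed respiratory displacement relative to the smoothed
        reference frame (exact oracle), and its interior-frame amplitude is
        bounded by the moving-average gain.

        The reference frame itself is smoothed with a truncated edge window,
        which contributes a constant offset to every displacement; the gain
        bound therefore applies to the series around its own level, not to
        the raw distance from identity.
        """
        amp = 1.5
        motion = MotionModel(drift_amplitude=(0,) * 6, mask_drift_amplitude=(0,) * 6,
                             resp_amplitude_mm=(0.0, amp, 0.0), thigh_amplitude_mm=0.0)
        cfg = SceneConfig(layout="abdominal", pixel_noise_px=0.0, dropout=0.0,
                          duration_s=300.0, seed=4, motion=motion)
        rec = simulate_intrafraction(cfg, with_detections=False)
        result = track_sequence(rec.clouds, TrackConfig(setup_type="abdominal"))
        resp = np.array([motion.respiration(t)[1] for t in rec.times])[:, None]
        sm = smooth_series(resp, 5)[:, 0]
        ap = np.array([tr.translation[1] for tr in result.body])
        # exact oracle: all respiratory markers move together, so the body
        # fit is the pure translation sm(t) - sm(0)
        np.testing.assert_allclose(ap, sm - sm[0], atol=1e-9)
        w = 2 * np.pi / motion.resp_period_s
        gain = abs(np.sin(5 * w * 5.0 / 2) / (5 * np.sin(w * 5.0 / 2)))
        interior = ap[2:-2] - (sm[2:-2].mean() - sm[0])
        assert np.abs(interior).max() <= gain * amp * 1.05 + 1e-9

    def test_thigh_markers_reported_not_registered(self, abdominal_layout):
        moved = abdominal_layout.points.copy()
        i10 = abdominal_layout.index("A10")
        moved[i10] += (0.0, 0.4, -0.2)
        frames = [abdominal_layout,
                  abdominal_layout.with_points(moved, time_s=5.0)]
        result = track_sequence(frames, TrackConfig(setup_type="abdominal", smooth=False))
        np.testing.assert_allclose(result.thigh_displacement["A10"][1], (0.0, 0.4, -0.2),
                                   atol=1e-12)
        np.testing.assert_allclose(result.thigh_displacement["A11"][1], 0.0, atol=1e-12)
        # the nudged thigh marker does not leak into the body transform
        assert result.body[1].is_close(RigidTransform.identity(), atol=1e-9)
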