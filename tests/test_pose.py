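"""Head-pose estimation: Euler conventions, PnP recovery, QC semantics, I/O."""

import numpy as np
import pytest

from tests.conftest import random_rotation
from thermopose.pose import (
    LANDMARK_LABELS,
    CameraModel,
    HeadModel3D,
    LandmarkObservation,
    default_head_template,
    euler_to_rotation,
    poses_to_dataframe,
    project_points,
    qc_filter,
    read_head_template,
    read_landmarks_csv,
    reprojection_residuals,
    rotation_to_euler,
    solve_pnp,
)

TRANSLATION = np.array([0.0, 0.0, 500.0])


def observe(pitch, yaw, roll, template, camera, *, translation=TRANSLATION,
            noise_px=0.0, rng=None, labels=None, frame_id="f"):
    """Exact (optionally noisy) projection of the template under a pose."""
    r = euler_to_rotation(pitch, yaw, roll)
    labels = labels or list(template.points)
    uv = project_points(template.array(labels), r, translation, camera)
    if noise_px > 0:
        uv = uv + rng.normal(0.0, noise_px, uv.shape)
    return LandmarkObservation(frame_id=frame_id,
                               landmarks={lab: tuple(p) for lab, p in zip(labels, uv)})


class TestEuler:
    def test_identity(self):
        p, y, r, gimbal = rotation_to_euler(np.eye(3))
        assert (p, y, r) == (0.0, 0.0, 0.0) and not gimbal

    def test_round_trip_10000_random_rotations(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        n = 0
        while n < 10_000:
            m = random_rotation(rng)
            p, y, r, gimbal = rotation_to_euler(m)
            if gimbal:
                continue
            back = euler_to_rotation(p, y, r)
            worst = max(worst, np.abs(back - m).max())
            n += 1
        assert worst < 1e-6

    def test_orthonormal_det_plus_one(self):
        m = euler_to_rotation(12.0, -47.0, 5.0)
        np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-12)

    def test_yaw_minus_90_faces_camera(self, template, camera):
        # at yaw=-90 the bill (template +x axis) points toward the camera
        # (-z in head frame maps toward the optical axis direction)
        r = euler_to_rotation(0.0, -90.0, 0.0)
        bill_dir = r @ np.array([1.0, 0.0, 0.0])
        assert bill_dir[2] == pytest.approx(-1.0, abs=1e-12)

    def test_gimbal_lock_flagged(self):
        m = euler_to_rotation(90.0, 30.0, 0.0)
        p, y, r, gimbal = rotation_to_euler(m)
        assert gimbal
        # convention: roll forced to 0 at the singularity, rotation preserved
        assert r == 0.0
        np.testing.assert_allclose(euler_to_rotation(p, y, r), m, atol=1e-9)


class TestSolvePnP:
    def test_identity_pose(self, template, camera):
        obs = observe(0.0, 0.0, 0.0, template, camera)
        est = solve_pnp(obs, template, camera)
        assert abs(est.pitch_deg) < 1e-6
        assert abs(est.yaw_deg) < 1e-6
        assert abs(est.roll_deg) < 1e-6
        assert est.mean_residual_px < 1e-6
        np.testing.assert_allclose(est.translation, TRANSLATION, atol=1e-3)

    def test_yaw_30_recovered(self, template, camera):
        obs = observe(0.0, 30.0, 0.0, template, camera)
        est = solve_pnp(obs, template, camera)
        assert est.yaw_deg == pytest.approx(30.0, abs=1e-4)

    def test_noiseless_random_poses(self, template, camera):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p, y, r = rng.uniform(-55, 55), rng.uniform(-85, 60), rng.uniform(-55, 55)
            est = solve_pnp(observe(p, y, r, template, camera), template, camera)
            assert abs(est.pitch_deg - p) < 1e-4
            assert abs(est.yaw_deg - y) < 1e-4
            assert abs(est.roll_deg - r) < 1e-4

    def test_four_point_minimal_case(self, template, camera):
        labels = ["bill_tip", "left_eye_center", "right_eye_center",
                  "upper_caudal_cyr"]
        obs = observe(5.0, -20.0, 3.0, template, camera, labels=labels)
        est = solve_pnp(obs, template, camera)
        assert est.yaw_deg == pytest.approx(-20.0, abs=1e-3)

    def test_yaw_equivariance(self, template, camera):
        # solving a projection at extra yaw delta shifts recovered yaw by delta
        base = solve_pnp(observe(4.0, 10.0, -6.0, template, camera),
                         template, camera)
        for delta in (-25.0, 15.0, 40.0):
            shifted = solve_pnp(observe(4.0, 10.0 + delta, -6.0, template, camera),
                                template, camera)
            assert shifted.yaw_deg - base.yaw_deg == pytest.approx(delta, abs=0.1)

    def test_scale_invariance(self, camera, template):
        # scaling the model and translation together leaves the image unchanged;
        # recovered rotation must be identical
        big = template.scaled(2.0)
        obs = observe(8.0, -35.0, 2.0, big, camera, translation=2.0 * TRANSLATION)
        est = solve_pnp(obs, big, camera)
        assert est.yaw_deg == pytest.approx(-35.0, abs=1e-4)

    def test_planar_model_fallback(self, camera):
        # z=0 plane model exercises the homography path
        model = HeadModel3D(points={
            "bill_tip": (55.0, 8.0, 0.0),
            "upper_caudal_cyr": (0.0, -20.0, 0.0),
            "left_eye_center": (10.0, 0.0, 0.0),
            "right_eye_center": (30.0, -5.0, 0.0),
            "lower_caudal_mandible": (5.0, 15.0, 0.0),
        })
        obs = observe(6.0, 25.0, -4.0, model, camera)
        est = solve_pnp(obs, model, camera)
        assert est.yaw_deg == pytest.approx(25.0, abs=1e-3)
        assert est.mean_residual_px < 1e-4

    def test_too_few_points_raises(self, template, camera):
        labels = ["bill_tip", "upper_caudal_cyr", "left_eye_center",
                  "right_eye_center"]
        obs = observe(0, 0, 0, template, camera, labels=labels)
        # model missing one of the observed labels -> only 3 correspondences
        model3 = HeadModel3D(points={k: template.points[k] for k in labels})
        del model3.points["upper_caudal_cyr"]
        with pytest.raises(ValueError, match=">= 4"):
            solve_pnp(obs, model3, camera)

    def test_collinear_template_rejected_at_construction(self):
        with pytest.raises(ValueError, match="collinear"):
            HeadModel3D(points={
                "bill_tip": (0.0, 0.0, 0.0),
                "upper_caudal_cyr": (10.0, 0.0, 0.0),
                "left_eye_center": (20.0, 0.0, 0.0),
                "right_eye_center": (30.0, 0.0, 0.0),
            })

    def test_collinear_observed_subset_raises(self, camera):
        # the model is valid overall, but the observed labels form a line
        collinear = ["bill_tip", "upper_caudal_cyr", "left_eye_center",
                     "right_eye_center"]
        pts = {lab: (10.0 * i, 0.0, 0.0) for i, lab in enumerate(collinear)}
        pts["lower_caudal_mandible"] = (5.0, 20.0, 7.0)
        model = HeadModel3D(points=pts)
        uv = project_points(model.array(collinear), np.eye(3), TRANSLATION, camera)
        obs = LandmarkObservation(frame_id="f", landmarks={
            lab: tuple(p) for lab, p in zip(collinear, uv)})
        with pytest.raises(ValueError, match="collinear"):
            solve_pnp(obs, model, camera)


class TestResiduals:
    def test_generating_pose_zero_residuals(self, template, camera):
        obs = observe(3.0, -40.0, 1.0, template, camera)
        est = solve_pnp(obs, template, camera)
        res, mean = reprojection_residuals(est, obs, template, camera)
        assert mean < 1e-6 and np.all(res < 1e-5)

    def test_pythagorean_shift(self, template, camera):
        obs = observe(0.0, 0.0, 0.0, template, camera)
        est = solve_pnp(obs, template, camera)
        shifted = LandmarkObservation(frame_id="f", landmarks={
            lab: (u + 3.0, v + 4.0) for lab, (u, v) in obs.landmarks.items()})
        res, mean = reprojection_residuals(est, shifted, template, camera)
        np.testing.assert_allclose(res, 5.0, atol=1e-5)
        assert mean == pytest.approx(5.0, abs=1e-5)

    def test_mean_matches_hand_oracle(self, template, camera):
        rng = np.random.default_rng(7)
        obs = observe(2.0, 12.0, -3.0, template, camera, noise_px=2.0, rng=rng)
        est = solve_pnp(obs, template, camera)
        labels = [lab for lab in obs.labels if lab in template.points]
        proj = project_points(template.array(labels), est.rotation_matrix,
                              est.translation, camera)
        uv = np.array([obs.landmarks[lab] for lab in labels])
        expect = np.sqrt(((proj - uv) ** 2).sum(axis=1))
        res, mean = reprojection_residuals(est, obs, template, camera)
        np.testing.assert_allclose(res, expect, atol=1e-9)
        assert mean == pytest.approx(expect.mean(), abs=1e-9)


class TestQCFilter:
    @staticmethod
    def _pose(frame_id, residual):
        from thermopose.pose import PoseEstimate
        return PoseEstimate(frame_id=frame_id, rotation_matrix=np.eye(3),
                            pitch_deg=0, yaw_deg=0, roll_deg=0,
                            translation=TRANSLATION,
                            mean_residual_px=residual, retained=True)

    def test_boundary_semantics(self):
        retained, report = qc_filter([self._pose("a", 25.0),
                                      self._pose("b", 25.01)], 25.0)
        assert [p.frame_id for p in retained] == ["a"]
        assert report["excluded_frames"] == ["b"]

    def test_empty_input(self):
        retained, report = qc_filter([], 25.0)
        assert retained == [] and report["n_excluded"] == 0

    def test_exclusion_count_matches_brute_force(self):
        rng = np.random.default_rng(3)
        residuals = rng.uniform(0, 50, 200)
        poses = [self._pose(f"f{i}", r) for i, r in enumerate(residuals)]
        retained, report = qc_filter(poses, 25.0)
        assert report["n_excluded"] == int((residuals > 25.0).sum())
        assert report["n_retained"] + report["n_excluded"] == 200

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            qc_filter([], 0.0)


class TestModelAndIO:
    def test_template_labels_match_enumeration(self, template):
        assert set(template.points) == set(LANDMARK_LABELS)
        assert len(LANDMARK_LABELS) == 9

    def test_observation_label_validation(self):
        with pytest.raises(ValueError, match="unknown"):
            LandmarkObservation(frame_id="f", landmarks={
                "nose": (0, 0), "bill_tip": (0, 0),
                "upper_caudal_cyr": (0, 0), "left_eye_center": (0, 0)})

    def test_observation_count_bounds(self):
        with pytest.raises(ValueError):
            LandmarkObservation(frame_id="f", landmarks={
                "bill_tip": (0, 0), "upper_caudal_cyr": (0, 0)})

    def test_landmarks_csv_round_trip(self, tmp_path, template, camera):
        obs = observe(5.0, -10.0, 0.0, template, camera, frame_id="t_000")
        lines = ["frame_id,label,u_px,v_px"]
        for lab, (u, v) in obs.landmarks.items():
            lines.append(f"t_000,{lab},{u},{v}")
        p = tmp_path / "landmarks.csv"
        p.write_text("\n".join(lines))
        loaded = read_landmarks_csv(p)
        assert len(loaded) == 1
        est = solve_pnp(loaded[0], template, camera)
        assert est.yaw_deg == pytest.approx(-10.0, abs=1e-4)

    def test_template_csv_round_trip(self, tmp_path, template):
        lines = ["label,x_mm,y_mm,z_mm"]
        for lab, (x, y, z) in template.points.items():
            lines.append(f"{lab},{x},{y},{z}")
        p = tmp_path / "template.csv"
        p.write_text("\n".join(lines))
        loaded = read_head_template(p)
        for lab in template.points:
            np.testing.assert_allclose(loaded.points[lab], template.points[lab])

    def test_poses_to_dataframe_columns(self, template, camera):
        est = solve_pnp(observe(0, 0, 0, template, camera), template, camera)
        df = poses_to_dataframe([est])
        for col in ["frame_id", "pitch_deg", "yaw_deg", "roll_deg",
                    "mean_residual_px", "retained"]:
            assert col in df.columns
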