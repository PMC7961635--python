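"""Inverse kinematics: calibration, marker completion, per-frame solves,
stream resampling."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rtmsk import ModelError, forward_kinematics
from rtmsk.ik import (ImuCalibration, MarkerHistory, ObservationFrame,
                      ObservationSource, calibrate_imu_placement, complete_markers,
                      resample_streams, solve_frame, solve_stream)
from rtmsk.synthetic import (GaitParams, generate_gait_trajectory, make_fixture,
                             synthesize_markers)

YAW = np.array([0.0, 1.0, 0.0])


def _static_frames(model, transform=Rotation.identity(), n=3):
    fk = forward_kinematics(model, np.zeros(model.n_coordinates))
    return [ObservationFrame(0.1 * i, orientations={k: transform * v
                                                    for k, v in fk.imus.items()})
            for i in range(n)]


class TestImuCalibration:
    def test_identity_when_streams_in_model_frame(self, walker):
        cal = calibrate_imu_placement(walker, _static_frames(walker), "pelvis_imu")
        assert cal.heading.magnitude() < 1e-12
        assert cal.offset.magnitude() < 1e-12

    def test_global_yaw_offset_recovered(self, walker):
        yaw = Rotation.from_rotvec(np.deg2rad(30) * YAW)
        cal = calibrate_imu_placement(walker, _static_frames(walker, yaw), "pelvis_imu")
        truth = forward_kinematics(walker, np.zeros(9)).imus
        for name, rot in truth.items():
            err = (cal.apply(yaw * rot).inv() * rot).magnitude()
            assert err < 1e-9

    def test_heading_from_horizontal_projection(self, walker):
        # base sensor pitched 20 deg out of horizontal plus a 40 deg yaw:
        # the heading must recover only the yaw (projection oracle)
        yaw_angle = np.deg2rad(40)
        pitch = Rotation.from_rotvec(np.deg2rad(20) * np.array([0, 0, 1]))
        yaw = Rotation.from_rotvec(yaw_angle * YAW)
        cal = calibrate_imu_placement(walker, _static_frames(walker, yaw * pitch),
                                      "pelvis_imu")
        # oracle: horizontal projection of the disturbed anterior axis
        ant = (yaw * pitch).apply([1.0, 0.0, 0.0])
        h = ant - ant[1] * YAW
        h /= np.linalg.norm(h)
        expected = -np.arctan2(-h[2], h[0])
        got = cal.heading.as_rotvec() @ YAW
        assert np.isclose(got, expected, atol=1e-9)

    def test_base_imu_missing(self, walker):
        with pytest.raises(ModelError):
            calibrate_imu_placement(walker, _static_frames(walker), "nope")

    def test_vertical_anterior_axis_rejected(self, walker):
        tip = Rotation.from_rotvec(np.pi / 2 * np.array([0.0, 0.0, 1.0]))
        frames = _static_frames(walker, tip)
        with pytest.raises(ModelError, match="vertical"):
            calibrate_imu_placement(walker, frames, "pelvis_imu",
                                    earth_to_model=Rotation.identity())


class TestMarkerCompletion:
    def test_complete_frame_unchanged(self, walker, rng):
        q = rng.normal(0, 0.2, 9)
        fk = forward_kinematics(walker, q)
        frame = ObservationFrame(0.0, markers=dict(fk.markers))
        out, report = complete_markers(frame, walker, MarkerHistory())
        assert not report["flagged"] and not report["reconstructed"]
        for name in fk.markers:
            assert np.allclose(out.markers[name], fk.markers[name])

    def test_procrustes_reconstruction(self, walker, rng):
        q = rng.normal(0, 0.3, 9)
        fk = forward_kinematics(walker, q)
        frame = ObservationFrame(0.0, markers=dict(fk.markers))
        frame.markers["thigh_r_2"] = None            # 1 of 4 occluded
        out, report = complete_markers(frame, walker, MarkerHistory())
        assert report["reconstructed"] == ["thigh_r_2"]
        assert np.linalg.norm(out.markers["thigh_r_2"] - fk.markers["thigh_r_2"]) < 1e-9

    def test_whole_segment_occluded_holds_last_position(self, walker):
        fk0 = forward_kinematics(walker, np.zeros(9))
        history = MarkerHistory()
        history.update(ObservationFrame(0.0, markers=dict(fk0.markers)))
        frame = ObservationFrame(0.01, markers=dict(fk0.markers))
        for name in ("shank_r_1", "shank_r_2", "shank_r_3"):
            frame.markers[name] = None
        out, report = complete_markers(frame, walker, history)
        assert report["flagged"]
        assert set(report["held"]) == {"shank_r_1", "shank_r_2", "shank_r_3"}
        for name in report["held"]:
            assert np.allclose(out.markers[name], fk0.markers[name])


class TestSolveFrame:
    def test_marker_roundtrip(self, walker, rng):
        q_true = rng.normal(0, 0.3, 9)
        fk = forward_kinematics(walker, q_true)
        res = solve_frame(walker, ObservationFrame(0, markers=dict(fk.markers)),
                          np.zeros(9))
        assert np.max(np.abs(res.q - q_true)) < 1e-6
        assert res.converged

    def test_zero_weight_equals_removed_target(self, walker, rng):
        q_true = rng.normal(0, 0.3, 9)
        fk = forward_kinematics(walker, q_true)
        withw = ObservationFrame(0, markers=dict(fk.markers),
                                 marker_weights={"pelvis_top": 0.0})
        without = ObservationFrame(0, markers={k: v for k, v in fk.markers.items()
                                               if k != "pelvis_top"})
        qa = solve_frame(walker, withw, np.zeros(9)).q
        qb = solve_frame(walker, without, np.zeros(9)).q
        assert np.max(np.abs(qa - qb)) < 1e-10

    def test_orientation_only_tracking(self, pendulum):
        fk = forward_kinematics(pendulum, np.array([0.9]))
        res = solve_frame(pendulum, ObservationFrame(0, orientations=dict(fk.imus)),
                          np.zeros(1))
        assert abs(res.q[0] - 0.9) < 1e-6

    def test_descent_guarantee(self, walker, rng):
        # inconsistent (noisy) targets: returned objective never exceeds the
        # objective at the initial point
        q_true = rng.normal(0, 0.3, 9)
        fk = forward_kinematics(walker, q_true)
        noisy = {k: v + rng.normal(0, 0.02, 3) for k, v in fk.markers.items()}
        frame = ObservationFrame(0, markers=noisy)
        from rtmsk.ik import _residuals_jacobian
        q0 = rng.normal(0, 0.5, 9)
        res = solve_frame(walker, frame, q0)
        r0, _ = _residuals_jacobian(walker, q0, frame.visible_markers(), {}, {}, {},
                                    [], 1.0, with_jac=False)
        assert res.cost <= 0.5 * r0 @ r0 + 1e-12

    def test_no_targets_rejected(self, walker):
        with pytest.raises(ModelError):
            solve_frame(walker, ObservationFrame(0), np.zeros(9))

    def test_noise_monotonic_recovery_error(self, walker):
        """Marker-recovery RMSE grows with marker noise (statistically)."""
        sigmas = [0.0, 0.001, 0.003, 0.005]
        rmse = []
        rng = np.random.default_rng(7)
        for sigma in sigmas:
            errs = []
            for _ in range(20):
                q_true = rng.normal(0, 0.25, 9)
                fk = forward_kinematics(walker, q_true)
                markers = {k: v + rng.normal(0, sigma, 3) for k, v in fk.markers.items()}
                q = solve_frame(walker, ObservationFrame(0, markers=markers), q_true).q
                errs.append(np.mean((q - q_true) ** 2))
            rmse.append(np.sqrt(np.mean(errs)))
        assert all(a < b + 1e-12 for a, b in zip(rmse[:-1], rmse[1:]))

    def test_warm_start_tracks_smooth_trajectory(self, walker, gait_params):
        states = generate_gait_trajectory(walker, gait_params, 100.0, 0.5)
        frames = synthesize_markers(walker, states, 0.0, 0.0, 0)
        results = solve_stream(walker, frames, q0=states[0].q)
        for prev, cur, st0, st1 in zip(results[:-1], results[1:], states[:-1], states[1:]):
            dq_true = np.max(np.abs(st1.q - st0.q))
            assert np.max(np.abs(cur.q - prev.q)) <= dq_true + 1e-3


class TestResample:
    def test_uniform_source_passthrough(self):
        t = np.arange(0, 1, 0.01)
        xyz = np.column_stack([t, 2 * t, np.zeros_like(t)])
        out = resample_streams([ObservationSource(t, markers={"m": xyz})], 100.0)
        assert len(out) == len(t)
        assert np.allclose([fr.markers["m"] for fr in out], xyz)

    def test_two_offset_linear_sources_exact(self):
        t1 = np.arange(0, 1.001, 0.01)
        t2 = t1 + 0.005
        lin = lambda t: np.column_stack([3 * t + 1, -t, 0 * t])
        out = resample_streams([ObservationSource(t1, markers={"a": lin(t1)}),
                                ObservationSource(t2, markers={"b": lin(t2)})], 100.0)
        grid = np.array([fr.t for fr in out])
        assert np.isclose(grid[0], 0.005)
        for fr in out:
            assert np.allclose(fr.markers["a"], lin(np.array([fr.t]))[0], atol=1e-12)
            assert np.allclose(fr.markers["b"], lin(np.array([fr.t]))[0], atol=1e-12)

    def test_constant_rate_rotation_slerp(self):
        # 2 rad/s about z sampled at 20 Hz, resampled to 100 Hz
        ts = np.arange(0, 1.001, 0.05)
        rots = Rotation.from_rotvec(np.outer(2.0 * ts, [0, 0, 1]))
        out = resample_streams([ObservationSource(ts, orientations={"s": rots})], 100.0)
        for fr in out:
            truth = Rotation.from_rotvec([0, 0, 2.0 * fr.t])
            assert (fr.orientations["s"].inv() * truth).magnitude() < 1e-4

    def test_nonmonotone_rejected(self):
        with pytest.raises(ModelError):
            resample_streams([ObservationSource(np.array([0.0, 0.2, 0.1]),
                                                markers={"m": np.zeros((3, 3))})], 100.0)

    def test_empty_source_rejected(self):
        with pytest.raises(ModelError):
            resample_streams([ObservationSource(np.array([]))], 100.0)
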