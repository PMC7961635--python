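"""Ground reaction wrench prediction: totals, gait phases, distribution,
centre of pressure."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from rtmsk import GenState, GRAVITY, ModelError, com_kinematics
from rtmsk.grfm import (GaitPhaseState, GrfmConfig, LegPhaseDetector,
                        TransitionFunction, cop_scaling, cop_trajectory,
                        detect_gait_phase, distribute_wrench, predict_grfm,
                        total_wrench, walking_direction)
from rtmsk.synthetic import contact_indicator, ground_truth_grfm

G = 9.80665


class TestTotalWrench:
    def test_static_standing_equals_body_weight(self, walker):
        kin = com_kinematics(walker, walker.default_state())
        f, tau = total_wrench(walker, kin)
        assert np.allclose(f, [0.0, walker.total_mass * G, 0.0], atol=1e-9)

    def test_free_fall_zero_wrench(self, walker):
        a = np.zeros(9)
        a[walker.coordinate_index("pelvis_ty")] = -G
        kin = com_kinematics(walker, GenState(0, np.zeros(9), np.zeros(9), a))
        f, tau = total_wrench(walker, kin)
        assert np.allclose(f, 0, atol=1e-9) and np.allclose(tau, 0, atol=1e-9)

    def test_matches_per_segment_summation_oracle(self, walker, gait_states):
        st = gait_states[40]
        kin = com_kinematics(walker, st)
        f, tau = total_wrench(walker, kin)
        f_ref = np.zeros(3)
        tau_ref = np.zeros(3)
        for name, seg in walker.segments.items():
            k = kin[name]
            R = k.rotation.as_matrix()
            Iw = R @ seg.inertia @ R.T
            fi = seg.mass * (k.com_acceleration - GRAVITY)
            f_ref += fi
            tau_ref += (Iw @ k.angular_acceleration
                        + np.cross(k.angular_velocity, Iw @ k.angular_velocity)
                        + np.cross(k.com, fi))
        assert np.max(np.abs(f - f_ref)) < 1e-10
        assert np.max(np.abs(tau - tau_ref)) < 1e-10


class TestPhaseDetection:
    def test_always_stance_no_events(self):
        t = np.arange(100) / 100
        phases, events = detect_gait_phase(t, np.ones(100), 0.5, k=3)
        assert all(p == "stance" for p in phases)
        assert not events.heel_strikes["r"] and not events.toe_offs["r"]

    def test_heel_strike_at_first_sample_of_run(self):
        t = np.arange(30) / 100
        u = np.where(t >= 0.12, 1.0, 0.0)
        phases, events = detect_gait_phase(t, u, 0.5, k=3)
        assert events.heel_strikes["r"] == [pytest.approx(0.12)]
        assert phases[11] == "swing" and phases[14] == "stance"

    def test_short_blip_debounced(self):
        u = np.zeros(30)
        u[10:12] = 1.0                 # k-1 = 2 frame blip
        phases, events = detect_gait_phase(np.arange(30) / 100, u, 0.5, k=3)
        assert all(p == "swing" for p in phases)
        assert not events.heel_strikes["r"]

    def test_debounce_count_validated(self):
        with pytest.raises(ModelError):
            LegPhaseDetector(0.5, k=0)


class TestWalkingDirection:
    def test_identity_for_forward_facing(self):
        rots = [Rotation.identity()] * 5
        assert walking_direction(rots).magnitude() < 1e-12

    def test_constant_yaw_and_norm_preservation(self):
        psi = np.deg2rad(30)
        rot = Rotation.from_rotvec([0, psi, 0])
        heading = walking_direction([rot] * 4)
        assert np.isclose(heading.as_rotvec()[1], psi)
        f = np.array([120.0, -30.0, 40.0])
        assert np.isclose(np.linalg.norm(heading.inv().apply(f)), np.linalg.norm(f))

    def test_symmetric_oscillation_circular_mean(self):
        psi = 0.7
        rots = [Rotation.from_rotvec([0, psi + s, 0]) for s in
                np.deg2rad([-10, 10, -10, 10])]
        assert np.isclose(walking_direction(rots).as_rotvec()[1], psi, atol=1e-9)

    def test_empty_window_rejected(self):
        with pytest.raises(ModelError):
            walking_direction([])


class TestTransitionAndDistribution:
    def test_transition_boundary_values(self):
        ft = TransitionFunction()
        assert np.allclose(ft.force(0.0), 1.0) and np.allclose(ft.force(1.0), 0.0)
        s = np.linspace(0, 1, 200)
        vals = np.array([ft.force(si)[0] for si in s])
        assert np.all(np.diff(vals) <= 1e-12)

    def test_linear_and_custom_shapes(self):
        lin = TransitionFunction(shape="linear")
        assert np.allclose(lin.force(0.25), 0.75)
        tab = np.array([[0.0, 1, 1, 1], [0.5, 0.4, 0.5, 0.6], [1.0, 0, 0, 0]])
        cus = TransitionFunction(shape="custom", force_table=tab, moment_table=tab)
        assert np.allclose(cus.force(0.5), [0.4, 0.5, 0.6])

    def test_distribute_at_heel_strike_and_end(self):
        ft = TransitionFunction()
        f_tot = np.array([10.0, 700.0, 5.0])
        m_tot = np.array([1.0, 2.0, 40.0])
        cached_f, cached_m = f_tot.copy(), m_tot.copy()
        lead, trail = distribute_wrench(f_tot, m_tot, GaitPhaseState(), ft,
                                        t=0.0, t_hs=0.0, cached_f=cached_f,
                                        cached_m=cached_m, T_ds=0.1)
        assert np.allclose(trail[0], cached_f) and np.allclose(lead[0], 0)
        lead, trail = distribute_wrench(f_tot, m_tot, GaitPhaseState(), ft,
                                        t=0.1, t_hs=0.0, cached_f=cached_f,
                                        cached_m=cached_m, T_ds=0.1)
        assert np.allclose(trail[0], 0) and np.allclose(lead[0], f_tot)
        assert np.allclose(lead[1], m_tot)


class TestCopModel:
    def test_scaling_closed_form_points(self):
        T_ss = 0.44
        assert cop_scaling(0.0, T_ss) == pytest.approx(0.0, abs=1e-15)
        assert cop_scaling(T_ss, T_ss) == pytest.approx(1.0, abs=1e-12)
        assert cop_scaling(T_ss / 2, T_ss) == pytest.approx(0.5, abs=1e-12)

    def test_scaling_monotone_with_flat_ends(self):
        T_ss = 1.0
        s = np.array([cop_scaling(t, T_ss) for t in np.linspace(0, T_ss, 1000)])
        assert np.all(np.diff(s) >= -1e-12)
        h = 1e-6
        assert abs(cop_scaling(h, T_ss) - cop_scaling(0, T_ss)) / h < 1e-4
        assert abs(cop_scaling(T_ss, T_ss) - cop_scaling(T_ss - h, T_ss)) / h < 1e-4

    def test_nonpositive_period_rejected(self):
        with pytest.raises(ModelError):
            cop_scaling(0.1, 0.0)

    def test_cop_between_heel_and_mtp(self, walker):
        st = walker.default_state()
        st.q[walker.coordinate_index("pelvis_ty")] = 0.85
        kin = com_kinematics(walker, st)
        heel = cop_trajectory(walker, kin, "foot_r", 0.0)
        mtp = cop_trajectory(walker, kin, "foot_r", 1.0)
        mid = cop_trajectory(walker, kin, "foot_r", 0.5)
        assert np.allclose(heel, [-0.05, 0.0, 0.1], atol=1e-12)
        assert np.allclose(mtp, [0.15, 0.0, 0.1], atol=1e-12)
        # flat 0.2 m foot: sigma=0.5 lies 0.1 m anterior to the heel
        assert np.allclose(mid - heel, [0.1, 0.0, 0.0], atol=1e-12)


class TestPrediction:
    @pytest.fixture(scope="class")
    def prediction(self, walker, gait_params, gait_states):
        cfg = GrfmConfig(T_ds_default=gait_params.T_ds,
                         T_ss_default=gait_params.T_ss, debounce=1,
                         contact_measure=lambda leg, i, t:
                         contact_indicator(gait_params, leg, t))
        return predict_grfm(walker, gait_states, cfg)

    def test_conservation_every_sample(self, prediction):
        n = len(prediction.times)
        for i in range(n):
            s = prediction.wrenches["r"][i].force + prediction.wrenches["l"][i].force
            assert np.allclose(s, prediction.total_force[i], atol=1e-9)
            m = sum(prediction.wrenches[l][i].moment
                    + np.cross(prediction.wrenches[l][i].point,
                               prediction.wrenches[l][i].force) for l in "rl")
            assert np.allclose(m, prediction.total_moment[i], atol=1e-8)

    def test_roundtrip_against_ground_truth(self, walker, gait_params, gait_states,
                                            prediction):
        truth, events, *_ = ground_truth_grfm(walker, gait_states, gait_params)
        BW = walker.total_mass * G
        for leg in "rl":
            pf = np.array([w.force for w in prediction.wrenches[leg]])
            tf = np.array([w.force for w in truth[leg]])
            assert np.max(np.abs(pf - tf)) < 1e-6 * BW

    def test_events_within_one_frame_of_schedule(self, gait_params, prediction,
                                                 gait_states):
        t0, t1 = gait_states[0].t, gait_states[-1].t
        from rtmsk.synthetic import nominal_events
        sched = nominal_events(gait_params, t0, t1)
        for leg in "rl":
            got = prediction.events.heel_strikes[leg]
            expect = [t for t in sched.heel_strikes[leg]]
            assert len(got) == len(expect)
            assert np.max(np.abs(np.array(got) - np.array(expect))) <= 0.01 + 1e-9

    def test_period_estimates_consistent(self, gait_params, prediction):
        st = prediction.state
        assert abs(st.T_ds - gait_params.T_ds) <= 0.02 + 1e-9
        assert abs(st.T_ss - gait_params.T_ss) <= 0.02 + 1e-9

    def test_single_support_swing_leg_zero(self, gait_params, prediction, gait_states):
        for i, st in enumerate(gait_states):
            c_r = contact_indicator(gait_params, "r", st.t)
            c_l = contact_indicator(gait_params, "l", st.t)
            if c_r and not c_l:
                assert np.allclose(prediction.wrenches["l"][i].force, 0)
                assert np.allclose(prediction.wrenches["r"][i].force,
                                   prediction.total_force[i], atol=1e-9)
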