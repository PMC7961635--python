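"""Moment arms, polynomial surrogate and redundancy optimization."""

import numpy as np
import pytest

from rtmsk import ModelError, model_from_dict
from rtmsk.muscles import (build_moment_arm_model, fit_moment_arm_polynomials,
                           identify_spanned_dofs, moment_arm_matrix,
                           muscle_path_length, sample_moment_arms,
                           solve_muscle_redundancy)


def _two_link(muscle_path, extra_muscles=()):
    """Two-link chain (q1 at origin, q2 at (0,-0.5)) with configurable muscles."""
    inertia = [0.01, 0.0005, 0.01, 0, 0, 0]
    muscles = [{"name": "m0", "fmax": 1000.0, "path": muscle_path}]
    muscles += list(extra_muscles)
    return model_from_dict({
        "segments": [
            {"name": "a", "mass": 1.0, "inertia": inertia, "com": [0, -0.25, 0],
             "endpoints": {"distal": [0, -0.5, 0]}},
            {"name": "b", "mass": 1.0, "inertia": inertia, "com": [0, -0.25, 0]},
        ],
        "joints": [
            {"name": "j1", "type": "revolute", "parent": "ground", "child": "a",
             "coordinates": ["q1"]},
            {"name": "j2", "type": "revolute", "parent": "a", "child": "b",
             "offset_parent": [0, -0.5, 0], "coordinates": ["q2"]},
        ],
        "muscles": muscles,
    })


class TestMomentArms:
    def test_non_crossing_coordinate_is_zero(self):
        # muscle entirely distal to j1's child: crosses j2 only
        m = _two_link([["a", 0.05, -0.3, 0.0], ["b", 0.05, -0.2, 0.0]])
        for q2 in (-0.5, 0.0, 0.8):
            R = moment_arm_matrix(m, np.array([0.3, q2]))
            assert abs(R[0, 0]) < 1e-9          # q1 not crossed
            assert abs(R[0, 1]) > 1e-3

    def test_pin_joint_perpendicular_distance(self):
        # straight horizontal line passing 0.05 m from the j2 centre:
        # |moment arm| equals the perpendicular distance
        m = _two_link([["a", -0.2, -0.45, 0.0], ["b", 0.3, 0.05, 0.0]])
        R = moment_arm_matrix(m, np.zeros(2))
        assert np.isclose(abs(R[0, 1]), 0.05, atol=1e-6)

    def test_finite_difference_matches_analytic_derivative(self, walker):
        """Central differences vs the symbolic derivative of the hip flexor's
        path length over the hip angle."""
        import sympy as sp

        th = sp.symbols("th")
        origin = sp.Matrix([0.07, 0.05])            # pelvis point (sagittal)
        local = sp.Matrix([0.03, -0.15])            # thigh point
        rot = sp.Matrix([[sp.cos(th), -sp.sin(th)], [sp.sin(th), sp.cos(th)]])
        insertion = rot * local
        # both attachments sit in the same sagittal plane (the thigh frame is
        # itself offset laterally by the hip's z offset), so no z term
        length = sp.sqrt((origin - insertion).dot(origin - insertion))
        dldth = sp.lambdify(th, sp.diff(length, th))
        names = list(walker.muscles)
        i = names.index("hip_flex_r")
        j = walker.coordinate_index("hip_r")
        for angle in (-0.6, 0.0, 0.4, 1.0):
            q = np.zeros(9)
            q[j] = angle
            R = moment_arm_matrix(walker, q, coordinates=[j])
            assert np.isclose(R[i, j], -dldth(angle), atol=1e-6)

    def test_degenerate_path_rejected(self):
        m = _two_link([["a", 0.0, -0.5, 0.0], ["b", 0.0, 0.0, 0.0]])
        with pytest.raises(ModelError, match="zero-length"):
            muscle_path_length(m, "m0", np.zeros(2))


class TestSpannedDofs:
    def test_single_joint_muscle_spans_one_coordinate(self):
        m = _two_link([["a", 0.05, -0.3, 0.0], ["b", 0.05, -0.2, 0.0]])
        grid = {"q1": np.linspace(-0.8, 0.8, 5), "q2": np.linspace(-0.8, 0.8, 5)}
        _, samples = sample_moment_arms(m, grid)
        assert identify_spanned_dofs(samples)[0] == [1]   # crosses j2 only

    def test_biarticular_muscle_spans_exactly_two(self):
        # three-link chain; a muscle from link a to link c crosses j2 and j3
        inertia = [0.01, 0.0005, 0.01, 0, 0, 0]
        m = model_from_dict({
            "segments": [
                {"name": n, "mass": 1.0, "inertia": inertia, "com": [0, -0.25, 0]}
                for n in ("a", "b", "c")],
            "joints": [
                {"name": "j1", "type": "revolute", "parent": "ground", "child": "a",
                 "coordinates": ["q1"]},
                {"name": "j2", "type": "revolute", "parent": "a", "child": "b",
                 "offset_parent": [0, -0.5, 0], "coordinates": ["q2"]},
                {"name": "j3", "type": "revolute", "parent": "b", "child": "c",
                 "offset_parent": [0, -0.5, 0], "coordinates": ["q3"]},
            ],
            "muscles": [{"name": "biart", "fmax": 1000.0,
                         "path": [["a", -0.05, -0.3, 0.0], ["c", -0.05, -0.1, 0.0]]}],
        })
        grid = {c: np.linspace(-0.6, 0.6, 4) for c in ("q1", "q2", "q3")}
        _, samples = sample_moment_arms(m, grid)
        assert identify_spanned_dofs(samples)[0] == [1, 2]

    def test_all_zero_row_flagged_empty(self):
        samples = np.zeros((5, 2, 3))
        samples[:, 1, 2] = 0.04
        spans = identify_spanned_dofs(samples)
        assert spans[0] == [] and spans[1] == [2]

    def test_walker_antagonist_pairs_opposite_sign(self, walker):
        R = moment_arm_matrix(walker, np.zeros(9))
        names = list(walker.muscles)
        for joint, (flex, ext) in {
            "hip_r": ("hip_flex_r", "hip_ext_r"),
            "knee_r": ("knee_ext_r", "knee_flex_r"),
            "ankle_r": ("ankle_dorsi_r", "ankle_plantar_r"),
        }.items():
            j = walker.coordinate_index(joint)
            assert R[names.index(flex), j] * R[names.index(ext), j] < 0


class TestPolynomialFit:
    def test_constant_moment_arm_exact(self):
        pts = np.linspace(-1, 1, 9)[:, None]
        samples = np.full((9, 1, 1), 0.04)
        mam = fit_moment_arm_polynomials(pts, samples, ["m"], [[0]], degree=0)
        assert mam.max_residual < 1e-12
        assert np.isclose(mam.evaluate(np.array([0.3]))[0, 0], 0.04)

    def test_quadratic_coefficients_recovered(self):
        rngs = np.linspace(-1, 1, 9)
        pts = np.array([[a, b] for a in rngs for b in rngs])
        poly = lambda x: 0.03 + 0.01 * x[:, 0] - 0.02 * x[:, 1] ** 2 \
            + 0.005 * x[:, 0] * x[:, 1]
        samples = poly(pts).reshape(-1, 1, 1)
        pts_full = np.column_stack([pts, np.zeros(len(pts))])  # 3-coordinate model
        samples3 = np.zeros((len(pts), 1, 3))
        samples3[:, 0, 0] = samples[:, 0, 0]
        mam = fit_moment_arm_polynomials(pts_full, samples3, ["m"], [[0, 1]], degree=2)
        assert mam.max_residual < 1e-10
        for x in ([0.3, -0.4, 0.0], [0.9, 0.9, 0.0]):
            x = np.array(x)
            assert np.isclose(mam.evaluate(x)[0, 0], poly(x[None, :2])[0], atol=1e-10)

    def test_surrogate_matches_samples_within_reported_residual(self, walker):
        mam = build_moment_arm_model(walker, points_per_dof=7, degree=4)
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = np.zeros(9)
            q[3:] = rng.uniform(-0.9, 0.9, 6)
            R_true = moment_arm_matrix(walker, q)
            R_poly = mam.evaluate(q).T
            assert np.max(np.abs(R_true - R_poly)) <= 5 * mam.max_residual

    def test_insufficient_samples_rejected(self):
        pts = np.linspace(-1, 1, 3)[:, None]
        samples = np.random.default_rng(0).normal(0, 0.01, (3, 1, 1))
        with pytest.raises(ModelError):
            fit_moment_arm_polynomials(pts, samples, ["m"], [[0]], degree=4)


class TestRedundancySolver:
    def test_zero_torque_zero_forces(self):
        out = solve_muscle_redundancy(np.array([[0.05, -0.05]]), [0.0],
                                      [1000.0, 1000.0])
        assert np.allclose(out.forces, 0, atol=1e-9) and out.objective < 1e-15

    def test_symmetric_agonists_share_load_kkt(self):
        # KKT closed form f_i = tau r_i F_i^2 / sum r^2 F^2 -> 500 N each
        out = solve_muscle_redundancy(np.array([[0.05, 0.05]]), [50.0],
                                      [1000.0, 1000.0], p=2)
        assert np.allclose(out.forces, [500.0, 500.0], atol=1e-6)
        assert out.residual_norm < 1e-9

    def test_antagonist_stays_silent(self):
        # brute force over the feasible line f1 = (tau + 0.05 f2)/0.05
        out = solve_muscle_redundancy(np.array([[0.05, -0.05]]), [50.0],
                                      [1000.0, 1000.0], p=2)
        f2 = np.linspace(0, 3000, 30001)
        f1 = (50.0 + 0.05 * f2) / 0.05
        best = np.argmin((f1 / 1000) ** 2 + (f2 / 1000) ** 2)
        assert np.allclose(out.forces, [f1[best], f2[best]], atol=1e-3)
        assert np.allclose(out.forces, [1000.0, 0.0], atol=1e-5)

    @pytest.mark.parametrize("p", [2, 3])
    def test_beats_brute_force_grid(self, p):
        R = np.array([[0.05, 0.03, 0.04]])
        tau = np.array([40.0])
        fmax = np.array([1000.0, 800.0, 1200.0])
        out = solve_muscle_redundancy(R, tau, fmax, p=p)
        assert out.residual_norm <= 1e-6 * 41
        # parametrize the feasible plane by (f2, f3) >= 0
        f2, f3 = np.meshgrid(np.linspace(0, 900, 301), np.linspace(0, 900, 301))
        f1 = (tau[0] - R[0, 1] * f2 - R[0, 2] * f3) / R[0, 0]
        ok = f1 >= 0
        obj = (np.abs(f1 / fmax[0]) ** p + (f2 / fmax[1]) ** p
               + (f3 / fmax[2]) ** p) / p
        assert out.objective <= np.min(obj[ok]) + 1e-8

    def test_warm_start_same_solution(self, rng):
        R = rng.normal(0, 0.05, (3, 8))
        fmax = rng.uniform(500, 2000, 8)
        f_feas = rng.uniform(0, 300, 8)
        tau = R @ f_feas
        cold = solve_muscle_redundancy(R, tau, fmax, p=2)
        warm = solve_muscle_redundancy(R, tau, fmax, p=2,
                                       warm_start=cold.forces + rng.normal(0, 5, 8))
        denom = 1 + np.abs(cold.forces)
        assert np.max(np.abs(cold.forces - warm.forces) / denom) < 1e-5

    def test_fmax_scaling_leaves_solution_invariant(self):
        R = np.array([[0.05, 0.05, -0.04]])
        fmax = np.array([1000.0, 800.0, 900.0])
        a = solve_muscle_redundancy(R, [30.0], fmax, p=2)
        b = solve_muscle_redundancy(R, [30.0], 2 * fmax, p=2)
        assert np.allclose(a.forces, b.forces, atol=1e-4)
        assert np.isclose(b.objective, a.objective / 4, rtol=1e-4)
        assert b.residual_norm <= 1e-6 * 31

    def test_infeasible_flagged_with_fallback(self):
        out = solve_muscle_redundancy(np.array([[0.05, 0.03]]), [-10.0],
                                      [1000.0, 1000.0], p=2)
        assert not out.feasible
        assert out.residual_norm > 1.0
        assert np.all(out.forces >= -1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ModelError):
            solve_muscle_redundancy(np.eye(2), [1, 1], [1.0, 1.0], p=4)
        with pytest.raises(ModelError):
            solve_muscle_redundancy(np.eye(2), [1, 1], [0.0, 1.0])


def test_gait_frames_feasible_and_nonnegative(walker, gait_states):
    """Every frame of the synthetic gait balances within tolerance with
    nonnegative forces."""
    from rtmsk import recursive_newton_euler

    mam = build_moment_arm_model(walker)
    fmax = np.array([m.fmax for m in walker.muscles.values()])
    warm = None
    for st in gait_states[::25]:
        tau = recursive_newton_euler(walker, st).actuated
        R = mam.evaluate(st.q, actuated_slice=slice(walker.n_base, None))
        out = solve_muscle_redundancy(R, tau, fmax, p=2, warm_start=warm)
        warm = out.forces
        assert out.residual_norm <= 1e-6 * (1 + np.linalg.norm(tau))
        assert np.min(out.forces) >= -1e-9
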