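"""Synthetic data generation: bundled toy models, analytic gait trajectories,
noisy marker/IMU observation streams and dynamically consistent ground-truth
ground-reaction wrenches.

The gait trajectory is a band-limited Fourier series per coordinate (periodic
joint angles plus constant-speed base progression), so first and second
derivatives are available in closed form. Gait events follow a fixed cycle
schedule: right heel-strike at multiples of the cycle duration T, each
double-support phase lasting ``ds_fraction * T``. Ground-truth per-leg
wrenches apply the same smooth-transition rules as the predictor but driven
by the exact schedule, which makes the synthetic trial a machine-precision
round-trip target for the prediction pipeline while the wrench total remains
dynamically consistent with the kinematics by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .dynamics import ExternalWrench
from .grfm import (GaitEvents, TransitionFunction, cop_scaling, cop_trajectory,
                   total_wrench, walking_direction)
from .ik import ObservationFrame
from .model import GenState, Model, ModelError, com_kinematics, load_model

FIXTURES = ("pendulum", "double_pendulum", "planar_walker")
_REFERENCE_MASS = 75.0

# (harmonic k, amplitude, phase) terms per coordinate: q = offset + sum A sin(2 pi k t / T + phi)
_WALKER_TABLE: dict[str, tuple[float, list[tuple[int, float, float]]]] = {
    "pelvis_tx": (0.0, [(2, 0.01, 1.0)]),
    "pelvis_ty": (0.85, [(2, 0.015, 0.0)]),
    "pelvis_rz": (0.0, [(1, 0.03, 0.5)]),
    "hip_r": (0.0, [(1, 0.35, np.pi / 2), (2, 0.06, 0.0)]),
    "knee_r": (-0.25, [(1, 0.18, np.pi), (2, 0.15, -np.pi / 2)]),
    "ankle_r": (0.0, [(1, 0.12, 0.3), (2, 0.05, 1.2)]),
    "hip_l": (0.0, [(1, 0.35, 3 * np.pi / 2), (2, 0.06, np.pi)]),
    "knee_l": (-0.25, [(1, 0.18, 0.0), (2, 0.15, np.pi / 2)]),
    "ankle_l": (0.0, [(1, 0.12, 0.3 + np.pi), (2, 0.05, 1.2 + np.pi)]),
}


@dataclass
class GaitParams:
    """Study conditions of the synthetic walking trial.

    T: gait cycle duration (s); ds_fraction: duration of each of the two
    double-support phases as a fraction of T (in (0, 0.5)); speed: forward
    progression (m/s); noise levels emulate optical marker jitter (m),
    IMU orientation noise (rad) and slow yaw drift (rad/s); occlusion_rate is
    the per-marker-per-frame dropout probability.
    """

    T: float = 1.1
    ds_fraction: float = 0.1
    speed: float = 1.2
    angle_table: dict = field(default_factory=lambda: dict(_WALKER_TABLE))
    marker_noise: float = 0.0
    orientation_noise: float = 0.0
    occlusion_rate: float = 0.0
    imu_drift_rate: float = 0.0
    seed: int = 0
    t_start: float | None = None     # default: 0.3 T (inside right single support)

    def __post_init__(self):
        if not 0.0 < self.ds_fraction < 0.5:
            raise ModelError("ds_fraction must lie in (0, 0.5)")
        for s in (self.marker_noise, self.orientation_noise, self.occlusion_rate):
            if s < 0:
                raise ModelError("noise levels must be >= 0")

    @property
    def T_ds(self) -> float:
        return self.ds_fraction * self.T

    @property
    def T_ss(self) -> float:
        return 0.5 * self.T - self.T_ds

    @property
    def start(self) -> float:
        return 0.3 * self.T if self.t_start is None else self.t_start


def make_fixture(name: str, subject_mass: float = 75.0) -> Model:
    """Load a bundled fixture model; the walker's masses/inertias are scaled
    so its total mass equals ``subject_mass`` exactly."""
    if name not in FIXTURES:
        raise ModelError(f"unknown fixture {name!r}; choose from {FIXTURES}")
    path = resources.files("rtmsk") / "models" / f"{name}.yaml"
    model = load_model(str(path))
    if name == "planar_walker" and subject_mass != _REFERENCE_MASS:
        scale = subject_mass / _REFERENCE_MASS
        for seg in model.segments.values():
            seg.mass *= scale
            seg.inertia = seg.inertia * scale
    return model


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def generate_gait_trajectory(model: Model, params: GaitParams, fs: float,
                             duration: float) -> list[GenState]:
    """Analytic band-limited gait kinematics with exact derivatives.

    q_j(t) = offset_j + sum_k A sin(2 pi k t / T + phi); the base forward
    coordinate additionally progresses at the configured speed.
    """
    if fs < 50:
        raise ModelError("sampling rate must be >= 50 Hz")
    t0 = params.start
    n = int(round(duration * fs)) + 1
    times = t0 + np.arange(n) / fs
    w0 = 2.0 * np.pi / params.T
    states = []
    for t in times:
        q = np.zeros(model.n_coordinates)
        u = np.zeros(model.n_coordinates)
        a = np.zeros(model.n_coordinates)
        for j, name in enumerate(model.coordinate_names):
            offset, harmonics = params.angle_table.get(name, (0.0, []))
            q[j] = offset
            for k, amp, phase in harmonics:
                wk = k * w0
                q[j] += amp * np.sin(wk * t + phase)
                u[j] += amp * wk * np.cos(wk * t + phase)
                a[j] -= amp * wk ** 2 * np.sin(wk * t + phase)
        if "pelvis_tx" in model.coordinate_names:
            jx = model.coordinate_index("pelvis_tx")
            q[jx] += params.speed * (t - t0)
            u[jx] += params.speed
        states.append(GenState(float(t), q, u, a))
    return states


def pendulum_trajectory(model: Model, fs: float, duration: float,
                        amplitude: float = 0.6, freq: float = 0.8,
                        offset: float = 0.0) -> list[GenState]:
    """Sinusoidal single-coordinate trajectory with analytic derivatives
    (works for any 1-DoF fixture)."""
    n = int(round(duration * fs)) + 1
    w = 2 * np.pi * freq
    out = []
    for t in np.arange(n) / fs:
        q = offset + amplitude * np.sin(w * t)
        out.append(GenState(float(t), np.array([q]),
                            np.array([amplitude * w * np.cos(w * t)]),
                            np.array([-amplitude * w ** 2 * np.sin(w * t)])))
    return out


# ---------------------------------------------------------------------------
# observation synthesis
# ---------------------------------------------------------------------------

def synthesize_markers(model: Model, states: list[GenState], sigma: float = 0.0,
                       occlusion_rate: float = 0.0, seed: int = 0
                       ) -> list[ObservationFrame]:
    """Marker streams: FK positions + iid Gaussian noise per axis, with iid
    Bernoulli occlusions (missing markers set to None)."""
    from .model import forward_kinematics
    rng = np.random.default_rng(seed)
    frames = []
    for st in states:
        fk = forward_kinematics(model, st.q)
        markers: dict[str, np.ndarray | None] = {}
        for name, pos in fk.markers.items():
            if occlusion_rate > 0 and rng.random() < occlusion_rate:
                markers[name] = None
            else:
                markers[name] = pos + rng.normal(0.0, sigma, 3)
        frames.append(ObservationFrame(st.t, markers=markers))
    return frames


def synthesize_imu(model: Model, states: list[GenState], sigma_rot: float = 0.0,
                   drift_rate: float = 0.0, seed: int = 0) -> list[ObservationFrame]:
    """IMU orientation streams: FK orientations composed with small-angle
    Gaussian noise and a linear-in-time yaw drift (bias accumulation)."""
    from .model import forward_kinematics
    rng = np.random.default_rng(seed)
    frames = []
    t0 = states[0].t if states else 0.0
    for st in states:
        fk = forward_kinematics(model, st.q)
        drift = Rotation.from_rotvec([0.0, drift_rate * (st.t - t0), 0.0])
        oris = {}
        for name, rot in fk.imus.items():
            noise = Rotation.from_rotvec(rng.normal(0.0, sigma_rot, 3))
            oris[name] = drift * rot * noise
        frames.append(ObservationFrame(st.t, orientations=oris))
    return frames


# ---------------------------------------------------------------------------
# gait schedule and ground-truth wrenches
# ---------------------------------------------------------------------------

def _cycle_phase(t: float, T: float, tol: float = 1e-9) -> float:
    """Phase of t within a cycle of period T, robust to float jitter at the
    cycle boundary (values within tol of T wrap to exactly 0)."""
    tau = t % T
    return 0.0 if tau > T - tol else tau


def contact_indicator(params: GaitParams, leg: str, t: float) -> float:
    """Insole-like binary contact signal from the nominal cycle schedule
    (right heel-strike at integer multiples of T)."""
    stance_end = 0.5 * params.T + params.T_ds
    offset = 0.0 if leg == "r" else 0.5 * params.T
    tau = _cycle_phase(t - offset, params.T)
    return 1.0 if tau < stance_end - 1e-9 else 0.0


def nominal_events(params: GaitParams, t0: float, t1: float) -> GaitEvents:
    """Scheduled heel-strike/toe-off times inside [t0, t1]."""
    ev = GaitEvents()
    k0 = int(np.floor(t0 / params.T)) - 1
    k1 = int(np.ceil(t1 / params.T)) + 1
    for k in range(k0, k1 + 1):
        base = k * params.T
        for leg, hs in (("r", base), ("l", base + 0.5 * params.T)):
            if t0 <= hs <= t1:
                ev.heel_strikes[leg].append(hs)
            to = hs + 0.5 * params.T + params.T_ds
            if t0 <= to <= t1:
                ev.toe_offs[leg].append(to)
    for d in (ev.heel_strikes, ev.toe_offs):
        for leg in d:
            d[leg] = sorted(d[leg])
    return ev


def ground_truth_grfm(model: Model, states: list[GenState], params: GaitParams,
                      transition: TransitionFunction | None = None,
                      foot_segments: dict[str, str] | None = None):
    """Per-leg ground-truth wrenches from the exact schedule.

    The total wrench comes from the Newton-Euler sum over segments; the
    per-leg split applies the smooth-transition rules with the scheduled
    events, exact double/single-support durations, and the heel-to-mtp CoP
    progression. Feeding these wrenches into inverse dynamics yields base
    residuals at machine precision because the split conserves the total.

    Returns ``(wrenches, events, f_total, m_total)``.
    """
    transition = transition or TransitionFunction()
    feet = foot_segments or {"r": "foot_r", "l": "foot_l"}
    T, T_ds, T_ss = params.T, params.T_ds, params.T_ss
    kins = [com_kinematics(model, st) for st in states]
    times = np.array([st.t for st in states])
    totals = [total_wrench(model, k) for k in kins]
    f_tot = np.array([f for f, _ in totals])
    m_tot = np.array([m for _, m in totals])

    heading = walking_direction([k["pelvis"].rotation for k in kins])
    Rw = heading.inv()
    f_tot_w = Rw.apply(f_tot)
    m_tot_w = Rw.apply(m_tot)

    # cached walking-frame totals at each scheduled heel-strike present in
    # the stream (heel strikes align with the sampling grid by construction)
    def index_of(t_ev: float) -> int | None:
        i = int(round((t_ev - times[0]) * (len(times) - 1) / (times[-1] - times[0])))
        if 0 <= i < len(times) and abs(times[i] - t_ev) < 1e-9:
            return i
        return None

    wrenches: dict[str, list[ExternalWrench]] = {"r": [], "l": []}
    zero = np.zeros(3)
    for i, t in enumerate(times):
        tau = _cycle_phase(t, T)
        stance = {"r": contact_indicator(params, "r", t) > 0.5,
                  "l": contact_indicator(params, "l", t) > 0.5}
        leading = "r" if tau < 0.5 * T - 1e-9 else "l"
        split: dict[str, tuple[np.ndarray, np.ndarray, float | None]] = {}
        if stance["r"] and stance["l"]:
            t_hs = t - (tau if leading == "r" else tau - 0.5 * T)
            ih = index_of(t_hs)
            trailing = "l" if leading == "r" else "r"
            if ih is None:
                # heel strike predates the stream: fall back to single support
                # on the leading leg (mirrors the causal predictor)
                split[leading] = (f_tot_w[i], m_tot_w[i], None)
                split[trailing] = (zero, zero, None)
            else:
                s = (t - t_hs) / T_ds
                f_trail = f_tot_w[ih] * transition.force(s)
                m_trail = m_tot_w[ih] * transition.moment(s)
                split[trailing] = (f_trail, m_trail, 1.0)
                split[leading] = (f_tot_w[i] - f_trail, m_tot_w[i] - m_trail, 0.0)
        else:
            leg = "r" if stance["r"] else "l"
            other = "l" if leg == "r" else "r"
            # single support started at the other leg's scheduled toe-off
            t_to = t - _cycle_phase(t - T_ds if leg == "r" else t - 0.5 * T - T_ds, T)
            sigma = cop_scaling(min(t - t_to, T_ss), T_ss)
            split[leg] = (f_tot_w[i], m_tot_w[i], sigma)
            split[other] = (zero, zero, None)
        for leg in ("r", "l"):
            fw, mw, sigma = split[leg]
            fg = heading.apply(fw)
            mg = heading.apply(mw)
            cop = cop_trajectory(model, kins[i], feet[leg],
                                 0.0 if sigma is None else sigma)
            wrenches[leg].append(ExternalWrench(
                point=cop, force=fg, moment=mg - np.cross(cop, fg), frame="ground"))
    events = nominal_events(params, float(times[0]), float(times[-1]))
    return wrenches, events, f_tot, m_tot
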