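"""Marker- and IMU-based inverse kinematics.

Per-frame weighted least-squares tracking of experimental marker positions
and segment (IMU) orientations:

    min_q  1/2 w_c ||c(q)||^2 + 1/2 sum_i w_i ||r_i(q)||^2 + 1/2 sum_j w_j alpha_j(q)^2

where r_i is the experimental-minus-virtual marker offset, alpha_j the
geodesic angle between experimental and virtual sensor orientation, and c(q)
an optional holonomic-constraint residual (zero for tree models). Includes
IMU placement/heading calibration, rigid-body marker completion for occluded
markers, and multi-source stream resampling onto a uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .model import Model, ModelError, forward_kinematics

VERTICAL = np.array([0.0, 1.0, 0.0])
ANTERIOR = np.array([1.0, 0.0, 0.0])


@dataclass
class ObservationFrame:
    """One time-stamped set of marker/orientation targets.

    Missing targets are simply absent from the maps (or set to None).
    Weights default to 1 for every named target.
    """

    t: float
    markers: dict[str, np.ndarray | None] = field(default_factory=dict)
    orientations: dict[str, Rotation | None] = field(default_factory=dict)
    marker_weights: dict[str, float] = field(default_factory=dict)
    orientation_weights: dict[str, float] = field(default_factory=dict)

    def visible_markers(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(v, float) for k, v in self.markers.items()
                if v is not None and np.all(np.isfinite(v))}

    def visible_orientations(self) -> dict[str, Rotation]:
        return {k: v for k, v in self.orientations.items() if v is not None}

    def n_targets(self) -> int:
        return len(self.visible_markers()) + len(self.visible_orientations())


@dataclass
class ImuCalibration:
    """Constant orientation offset applied to every sensor stream."""

    earth_to_model: Rotation
    heading: Rotation
    offset: Rotation        # heading * earth_to_model, applied as offset * measured

    def apply(self, measured: Rotation) -> Rotation:
        return self.offset * measured


def calibrate_imu_placement(model: Model, static_frames: list[ObservationFrame],
                            base_imu: str,
                            earth_to_model: Rotation | None = None,
                            q_default: np.ndarray | None = None) -> ImuCalibration:
    """Estimate the constant earth-to-model + heading offset from a static pose.

    The subject stands in the model's default pose. Sensor orientations are
    averaged over the static frames; the heading rotation about the vertical
    aligns the horizontal projection of the base sensor's anterior axis with
    the model's anterior axis. The composed offset is applied identically to
    every sensor for the rest of the session.
    """
    if base_imu not in model.imus:
        raise ModelError(f"unknown base imu {base_imu!r}")
    earth_to_model = earth_to_model or Rotation.identity()
    stacks: dict[str, list[Rotation]] = {}
    for fr in static_frames:
        for name, rot in fr.visible_orientations().items():
            stacks.setdefault(name, []).append(rot)
    if base_imu not in stacks:
        raise ModelError(f"base imu {base_imu!r} absent from static frames")
    mean_rot = {name: Rotation.concatenate(rs).mean() for name, rs in stacks.items()}

    q0 = np.zeros(model.n_coordinates) if q_default is None else np.asarray(q_default, float)
    fk = forward_kinematics(model, q0)

    imu = model.imus[base_imu]
    # anterior axis of the base segment, estimated from the measurement and
    # taken from the model at the default pose
    seg_rot_meas = (earth_to_model * mean_rot[base_imu]) * imu.local_orientation.inv()
    ant_meas = seg_rot_meas.apply(ANTERIOR)
    ant_model = (fk.imus[base_imu] * imu.local_orientation.inv()).apply(ANTERIOR)

    def horizontal(v: np.ndarray, what: str) -> np.ndarray:
        h = v - (v @ VERTICAL) * VERTICAL
        n = np.linalg.norm(h)
        if n < 1e-6:
            raise ModelError(f"{what} anterior axis is vertical; heading undefined")
        return h / n

    hm = horizontal(ant_meas, "measured")
    hv = horizontal(ant_model, "model")
    angle = np.arctan2(np.cross(hm, hv) @ VERTICAL, hm @ hv)
    heading = Rotation.from_rotvec(angle * VERTICAL)
    return ImuCalibration(earth_to_model, heading, heading * earth_to_model)


# ---------------------------------------------------------------------------
# marker completion
# ---------------------------------------------------------------------------

class MarkerHistory:
    """Last seen world position per marker (for the hold fallback) and the
    per-segment visibility bookkeeping used by marker completion."""

    def __init__(self):
        self.last_position: dict[str, np.ndarray] = {}

    def update(self, frame: ObservationFrame) -> None:
        for name, pos in frame.visible_markers().items():
            self.last_position[name] = pos


def _kabsch(local: np.ndarray, world: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) minimizing ||R local + t - world|| (orthogonal
    Procrustes with the proper-rotation constraint)."""
    cl, cw = local.mean(axis=0), world.mean(axis=0)
    H = (local - cl).T @ (world - cw)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cw - R @ cl


def complete_markers(frame: ObservationFrame, model: Model,
                     history: MarkerHistory) -> tuple[ObservationFrame, dict]:
    """Reconstruct occluded markers.

    Markers missing on a segment that still shows >= 3 markers are rebuilt by
    the rigid (Kabsch/Procrustes) transform fitted from the visible markers'
    model-frame positions to their world positions. Segments with fewer
    visible markers fall back to each marker's last known position and the
    frame is flagged. Never hard-fails; returns a completion report.
    """
    visible = frame.visible_markers()
    by_segment: dict[str, list[str]] = {}
    for name, mdef in model.markers.items():
        if name in frame.markers or name in visible:
            by_segment.setdefault(mdef.segment, []).append(name)

    out = dict(frame.markers)
    report = {"reconstructed": [], "held": [], "dropped": [], "flagged": False}
    for segment, names in by_segment.items():
        missing = [n for n in names if n not in visible]
        if not missing:
            continue
        vis = [n for n in names if n in visible]
        if len(vis) >= 3:
            local = np.array([model.markers[n].local_position for n in vis])
            world = np.array([visible[n] for n in vis])
            R, t = _kabsch(local, world)
            for n in missing:
                out[n] = R @ model.markers[n].local_position + t
                report["reconstructed"].append(n)
        else:
            for n in missing:
                if n in history.last_position:
                    out[n] = history.last_position[n]
                    report["held"].append(n)
                else:
                    report["dropped"].append(n)
            report["flagged"] = True
    completed = ObservationFrame(frame.t, out, dict(frame.orientations),
                                 dict(frame.marker_weights), dict(frame.orientation_weights))
    history.update(completed)
    return completed, report


# ---------------------------------------------------------------------------
# per-frame solve
# ---------------------------------------------------------------------------

@dataclass
class IKResult:
    q: np.ndarray
    cost: float
    converged: bool
    marker_errors: dict[str, float]      # metres
    orientation_errors: dict[str, float]  # radians (geodesic)
    n_iterations: int


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def _dexpinv(phi: np.ndarray) -> np.ndarray:
    """Inverse right-trivialized differential of the rotation exponential:
    maps a body-frame angular perturbation to the change of the rotation
    vector (exact differential of the matrix log)."""
    theta = np.linalg.norm(phi)
    S = _skew(phi)
    if theta < 1e-8:
        c = 1.0 / 12.0 + theta ** 2 / 720.0
    else:
        c = (1.0 - theta * np.sin(theta) / (2.0 * (1.0 - np.cos(theta)))) / theta ** 2
    return np.eye(3) - 0.5 * S + c * (S @ S)


def _residuals_jacobian(model: Model, q: np.ndarray, markers, orientations,
                        mw, ow, constraints, wc, with_jac: bool = True):
    """Stacked weighted residuals and (optionally) their analytic Jacobian.

    Marker rows use the geometric point Jacobian (axis cross offset for
    revolute DoFs); orientation rows map the virtual segment's angular
    Jacobian through the differential of the rotation log.
    """
    from .model import tree_kinematics

    kin, dofs = tree_kinematics(model, q)
    n = model.n_coordinates
    parts, jac_parts = [], []
    for name, target in markers.items():
        mdef = model.markers[name]
        k = kin[mdef.segment]
        p = k.origin + k.rotation.apply(mdef.local_position)
        w = np.sqrt(mw.get(name, 1.0))
        parts.append(w * (p - target))
        if with_jac:
            J = np.zeros((3, n))
            for ci in model.coordinates_affecting(mdef.segment):
                d = dofs[ci]
                J[:, ci] = d.axis if d.kind == "pris" else np.cross(d.axis, p - d.point)
            jac_parts.append(w * J)
    for name, target in orientations.items():
        sdef = model.imus[name]
        Rv = kin[sdef.segment].rotation * sdef.local_orientation
        rel = Rv.inv() * target
        phi = rel.as_rotvec()
        w = np.sqrt(ow.get(name, 1.0))
        parts.append(w * phi)
        if with_jac:
            D = _dexpinv(phi)
            Rv_T = Rv.inv()
            J = np.zeros((3, n))
            for ci in model.coordinates_affecting(sdef.segment):
                d = dofs[ci]
                if d.kind == "rev":
                    # d(phi)/dq = -dexpinv(phi) R_v^T w_axis
                    J[:, ci] = -D @ Rv_T.apply(d.axis)
            jac_parts.append(w * J)
    for c in constraints:
        r = np.atleast_1d(np.asarray(c(q), float))
        parts.append(np.sqrt(wc) * r)
        if with_jac:
            # numeric rows for user-supplied constraint penalties
            J = np.zeros((len(r), n))
            h = 1e-7
            for j in range(n):
                qp = q.copy()
                qp[j] += h
                J[:, j] = (np.atleast_1d(c(qp)) - r) / h
            jac_parts.append(np.sqrt(wc) * J)
    resid = np.concatenate(parts) if parts else np.zeros(0)
    if not with_jac:
        return resid, None
    return resid, (np.vstack(jac_parts) if jac_parts else np.zeros((0, n)))


def solve_frame(model: Model, frame: ObservationFrame, q_init: np.ndarray,
                constraint_penalty_weight: float = 1.0,
                constraints: list | None = None,
                max_iterations: int = 100) -> IKResult:
    """Solve one IK frame by damped Gauss-Newton (trust-region reflective) on
    the stacked residuals, warm-started from ``q_init``.

    Guarantees descent: if the optimizer fails to improve on ``q_init`` the
    initial point is returned, flagged as non-converged.
    """
    q_init = np.asarray(q_init, float)
    if not np.all(np.isfinite(q_init)):
        raise ModelError("q_init must be finite")
    markers = frame.visible_markers()
    orientations = frame.visible_orientations()
    constraints = constraints or []
    if not markers and not orientations and not constraints:
        raise ModelError("frame has no usable targets")
    for name in markers:
        if name not in model.markers:
            raise ModelError(f"unknown marker {name!r}")
    for name in orientations:
        if name not in model.imus:
            raise ModelError(f"unknown imu {name!r}")

    args = (model, markers, orientations, frame.marker_weights,
            frame.orientation_weights, constraints, constraint_penalty_weight)

    def eval_at(q, with_jac=True):
        return _residuals_jacobian(args[0], q, *args[1:], with_jac=with_jac)

    # damped Gauss-Newton (Levenberg regularization, adaptive)
    q = q_init.copy()
    r, J = eval_at(q)
    cost0 = cost = 0.5 * float(r @ r)
    lam = 1e-6
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        g = J.T @ r
        if np.linalg.norm(g, np.inf) < 1e-12:
            converged = True
            break
        H = J.T @ J
        improved = False
        for _ in range(20):
            try:
                step = np.linalg.solve(H + lam * np.eye(len(q)), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            r_new, J_new = eval_at(q + step)
            cost_new = 0.5 * float(r_new @ r_new)
            if cost_new <= cost:
                q = q + step
                improved = True
                shrink = cost - cost_new
                r, J, cost = r_new, J_new, cost_new
                lam = max(lam * 0.3, 1e-12)
                if np.linalg.norm(step, np.inf) < 1e-12 or shrink < 1e-16 * (1 + cost):
                    converged = True
                break
            lam *= 10.0
        if converged or not improved:
            converged = converged or not improved and cost <= cost0
            break
    if cost > cost0:            # descent guarantee
        q, cost, converged = q_init.copy(), cost0, False

    fk = forward_kinematics(model, q)
    mark_err = {n: float(np.linalg.norm(fk.markers[n] - t)) for n, t in markers.items()}
    ori_err = {n: float(np.linalg.norm((fk.imus[n].inv() * t).as_rotvec()))
               for n, t in orientations.items()}
    return IKResult(q, float(cost), converged, mark_err, ori_err, n_iter)


def solve_stream(model: Model, frames: list[ObservationFrame],
                 q0: np.ndarray | None = None, **kwargs) -> list[IKResult]:
    """Sequential warm-started IK over a frame stream."""
    q = np.zeros(model.n_coordinates) if q0 is None else np.asarray(q0, float)
    out = []
    for fr in frames:
        r = solve_frame(model, fr, q, **kwargs)
        out.append(r)
        q = r.q
    return out


# ---------------------------------------------------------------------------
# stream resampling
# ---------------------------------------------------------------------------

@dataclass
class ObservationSource:
    """One sensor source: timestamps plus named marker/orientation channels."""

    times: np.ndarray
    markers: dict[str, np.ndarray] = field(default_factory=dict)       # (n, 3)
    orientations: dict[str, Rotation] = field(default_factory=dict)    # stacked

    def validate(self) -> None:
        t = np.asarray(self.times, float)
        if t.size == 0:
            raise ModelError("empty source")
        if np.any(np.diff(t) <= 0):
            raise ModelError("non-monotone timestamps")


def resample_streams(sources: list[ObservationSource], fs: float) -> list[ObservationFrame]:
    """Resample heterogeneous timestamped sources onto a shared uniform grid.

    Marker channels are linearly interpolated per axis; orientation channels
    are spherically interpolated (slerp). The grid spans the overlap of all
    sources at the requested rate, anchored at the latest stream start.
    """
    if not sources:
        raise ModelError("no sources")
    for s in sources:
        s.validate()
    t0 = max(float(np.asarray(s.times)[0]) for s in sources)
    t1 = min(float(np.asarray(s.times)[-1]) for s in sources)
    if t1 < t0:
        raise ModelError("sources do not overlap in time")
    n = int(np.floor((t1 - t0) * fs + 1e-9)) + 1
    grid = t0 + np.arange(n) / fs

    frames = [ObservationFrame(t) for t in grid]
    for src in sources:
        st = np.asarray(src.times, float)
        for name, xyz in src.markers.items():
            xyz = np.asarray(xyz, float)
            interp = np.column_stack([np.interp(grid, st, xyz[:, k]) for k in range(3)])
            for fr, row in zip(frames, interp):
                fr.markers[name] = row
        for name, rots in src.orientations.items():
            sl = Slerp(st, rots)
            out = sl(np.clip(grid, st[0], st[-1]))
            for i, fr in enumerate(frames):
                fr.orientations[name] = out[i]
    return frames
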