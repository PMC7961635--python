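"""Inverse dynamics: generalized forces from full kinematics + external loads.

The generalized forces are obtained by a forward Newton-Euler pass over the
tree (exact velocity/acceleration propagation in :func:`rtmsk.model.tree_kinematics`)
followed by projection of every segment's net inertial-minus-applied wrench
onto the elementary joint axes (Jacobian-transpose form of the recursive
Newton-Euler balance). For tree models this is algebraically identical to the
classic backward recursion.

The base (first) joint block of the result holds the residual forces/moments
of the floating base - the non-physical wrench that absorbs model/data
inconsistency and serves as a quality diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import GRAVITY, GenState, Model, ModelError, tree_kinematics


@dataclass
class ExternalWrench:
    """Application point + force + moment (the 9-vector GRF&M currency)."""

    point: np.ndarray
    force: np.ndarray
    moment: np.ndarray
    frame: str = "ground"

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        self.force = np.asarray(self.force, float)
        self.moment = np.asarray(self.moment, float)

    def validate(self) -> None:
        for v in (self.point, self.force, self.moment):
            if np.asarray(v).shape != (3,) or not np.all(np.isfinite(v)):
                raise ModelError("ExternalWrench entries must be finite 3-vectors")

    def moment_about(self, origin: np.ndarray) -> np.ndarray:
        """Equivalent moment when the wrench is resolved about ``origin``."""
        return self.moment + np.cross(self.point - origin, self.force)


@dataclass
class GeneralizedForces:
    """Generalized forces aligned with the model's coordinate order."""

    tau: np.ndarray
    n_base: int
    coordinate_names: list[str] = field(default_factory=list)

    @property
    def base(self) -> np.ndarray:
        return self.tau[:self.n_base]

    @property
    def actuated(self) -> np.ndarray:
        return self.tau[self.n_base:]


def _point_loads(model: Model, kin, external, point_forces):
    """Collect (segment, world point, force, moment) applied loads."""
    loads: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = {}
    for seg, wrench in external or []:
        if seg not in model.segments:
            raise ModelError(f"external wrench on unknown segment {seg!r}")
        wrench.validate()
        loads.setdefault(seg, []).append((wrench.point, wrench.force, wrench.moment))
    for seg, point, force in point_forces or []:
        if seg not in model.segments:
            raise ModelError(f"point force on unknown segment {seg!r}")
        loads.setdefault(seg, []).append(
            (np.asarray(point, float), np.asarray(force, float), np.zeros(3)))
    return loads


def net_segment_wrenches(model: Model, kin, external=None, point_forces=None,
                         gravity: np.ndarray = GRAVITY):
    """Per segment: net force and net moment (about the segment COM) that the
    joint structure must supply, i.e. inertial terms minus gravity and minus
    all applied loads."""
    loads = _point_loads(model, kin, external, point_forces)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, seg in model.segments.items():
        k = kin[name]
        R = k.rotation.as_matrix()
        Iw = R @ seg.inertia @ R.T
        F = seg.mass * (k.com_acceleration - gravity)
        M = Iw @ k.angular_acceleration + np.cross(
            k.angular_velocity, Iw @ k.angular_velocity)
        for point, force, moment in loads.get(name, []):
            F = F - force
            M = M - moment - np.cross(point - k.com, force)
        out[name] = (F, M)
    return out


def recursive_newton_euler(model: Model, state: GenState,
                           external: list[tuple[str, ExternalWrench]] | None = None,
                           point_forces=None,
                           gravity: np.ndarray = GRAVITY) -> GeneralizedForces:
    """Generalized forces balancing the equations of motion.

    Parameters
    ----------
    external
        ``(segment, ExternalWrench)`` pairs, wrench expressed in the ground
        frame with an application point (e.g. per-leg GRF&M).
    point_forces
        Optional ``(segment, world point, world force)`` triples (used for
        muscle path forces by the joint-reaction analysis).
    """
    state.validate(model.n_coordinates)
    kin, dofs = tree_kinematics(model, state.q, state.u, state.a)
    net = net_segment_wrenches(model, kin, external, point_forces, gravity)

    tau = np.zeros(model.n_coordinates)
    for i, dof in enumerate(dofs):
        for seg_name in model.subtree(dof.child_segment):
            F, M = net[seg_name]
            c = kin[seg_name].com
            if dof.kind == "pris":
                tau[i] += dof.axis @ F
            else:
                tau[i] += dof.axis @ (M + np.cross(c - dof.point, F))
    return GeneralizedForces(tau, model.n_base, list(model.coordinate_names))


def residual_report(forces: GeneralizedForces | list[GeneralizedForces]) -> dict:
    """Base-block residual summary (running RMS), the pipeline's consistency
    diagnostic: large residuals mean the supplied external loads and the
    kinematics disagree."""
    seq = [forces] if isinstance(forces, GeneralizedForces) else list(forces)
    if not seq:
        return {"n": 0, "rms": np.zeros(0), "max_abs": np.zeros(0)}
    base = np.array([gf.base for gf in seq])
    return {
        "n": len(seq),
        "coordinates": seq[0].coordinate_names[:seq[0].n_base],
        "rms": np.sqrt(np.mean(base ** 2, axis=0)),
        "max_abs": np.max(np.abs(base), axis=0),
    }


# -- test-support forward dynamics ------------------------------------------

def mass_matrix(model: Model, q: np.ndarray) -> np.ndarray:
    """Joint-space mass matrix assembled column-wise from unit-acceleration
    inverse dynamics (test/support use)."""
    n = model.n_coordinates
    zero = np.zeros(n)
    g0 = np.zeros(3)
    bias0 = recursive_newton_euler(
        model, GenState(0.0, q, zero, zero), gravity=g0).tau
    M = np.empty((n, n))
    for j in range(n):
        ej = np.zeros(n)
        ej[j] = 1.0
        M[:, j] = recursive_newton_euler(
            model, GenState(0.0, q, zero, ej), gravity=g0).tau - bias0
    return M


def forward_dynamics(model: Model, q, u, tau, external=None,
                     gravity: np.ndarray = GRAVITY) -> np.ndarray:
    """Accelerations from torques: solves M(q) a = tau - bias(q, u).

    Support utility for round-trip tests (not a simulation feature)."""
    n = model.n_coordinates
    bias = recursive_newton_euler(
        model, GenState(0.0, q, u, np.zeros(n)), external=external,
        gravity=gravity).tau
    return np.linalg.solve(mass_matrix(model, q), np.asarray(tau, float) - bias)
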