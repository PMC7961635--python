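"""Joint reaction analysis: loads transmitted through joint structures.

For each joint, the reaction wrench acting on the child segment (expressed in
the ground frame at the joint centre) balances the distal subtree: it equals
the subtree's inertial wrench minus gravity, muscle path forces and external
wrenches applied to the subtree. Muscle tensions act along the straight-line
path directions at every attachment/via point, equal and opposite on the
adjoining segments, so co-contraction raises joint compression without
changing the net joint moment.

Dynamic inconsistency between kinematics and applied loads is not
redistributed; it surfaces as the base joint's reaction, mirroring the
residual-force diagnostic of inverse dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ExternalWrench, _point_loads
from .model import GRAVITY, GenState, Model, ModelError, tree_kinematics


@dataclass
class JointReaction:
    """Reaction force/moment on the child segment, ground frame, at the joint
    centre."""

    joint: str
    child: str
    point: np.ndarray
    force: np.ndarray
    moment: np.ndarray


def muscle_path_forces(model: Model, q: np.ndarray, forces: np.ndarray,
                       muscle_names: list[str] | None = None
                       ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Convert muscle tensions into per-segment applied point forces.

    Each muscle pulls its attachment/via points toward the adjacent path
    points with its (nonnegative) tension. Returns (segment, world point,
    world force) triples.
    """
    names = muscle_names or list(model.muscles)
    forces = np.atleast_1d(np.asarray(forces, float))
    if forces.shape != (len(names),):
        raise ModelError(f"expected {len(names)} muscle forces, got {forces.shape}")
    if np.any(forces < -1e-9):
        raise ModelError("muscle tensions must be nonnegative")
    kin, _ = tree_kinematics(model, q)
    out = []
    for name, f in zip(names, forces):
        if f <= 0.0:
            continue
        mus = model.muscles[name]
        pts = [kin[seg].origin + kin[seg].rotation.apply(loc) for seg, loc in mus.path]
        for k, (seg, _) in enumerate(mus.path):
            pull = np.zeros(3)
            for nb in (k - 1, k + 1):
                if 0 <= nb < len(pts):
                    d = pts[nb] - pts[k]
                    norm = np.linalg.norm(d)
                    if norm < 1e-12:
                        raise ModelError(f"muscle {name}: zero-length path segment")
                    pull += d / norm
            out.append((seg, pts[k], f * pull))
    return out


def joint_reaction_analysis(model: Model, state: GenState,
                            muscle_forces: np.ndarray | None = None,
                            external: list[tuple[str, ExternalWrench]] | None = None,
                            muscle_names: list[str] | None = None,
                            gravity: np.ndarray = GRAVITY) -> list[JointReaction]:
    """Reaction wrench at every joint from distal-to-proximal bookkeeping.

    Inputs should be dynamically consistent: the filtered state, the per-leg
    external wrenches and the solved muscle tensions of the same frame.
    """
    state.validate(model.n_coordinates)
    kin, _ = tree_kinematics(model, state.q, state.u, state.a)

    point_forces = []
    if muscle_forces is not None:
        point_forces = muscle_path_forces(model, state.q, muscle_forces, muscle_names)
    loads = _point_loads(model, kin, external, point_forces)

    # net (inertial - applied) force and moment-about-COM per segment
    net: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, seg in model.segments.items():
        k = kin[name]
        R = k.rotation.as_matrix()
        Iw = R @ seg.inertia @ R.T
        F = seg.mass * (k.com_acceleration - gravity)
        M = Iw @ k.angular_acceleration + np.cross(k.angular_velocity,
                                                   Iw @ k.angular_velocity)
        for point, force, moment in loads.get(name, []):
            F = F - force
            M = M - moment - np.cross(point - k.com, force)
        net[name] = (F, M)

    reactions = []
    for joint in model.joints:
        child = joint.child
        anchor = kin[child].origin + kin[child].rotation.apply(joint.offset_child)
        F = np.zeros(3)
        M = np.zeros(3)
        for seg in model.subtree(child):
            Fi, Mi = net[seg]
            F += Fi
            M += Mi + np.cross(kin[seg].com - anchor, Fi)
        reactions.append(JointReaction(joint.name, child, anchor, F, M))
    return reactions
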