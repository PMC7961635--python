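"""Rigid-body tree model: definition, forward kinematics and COM kinematics.

The model is a tree of rigid segments rooted at the ground. Joints are
revolute (1 DoF), free planar (2 translations + 1 rotation, 3 DoF) or free
spatial (3 translations + 3 intrinsic rotations, 6 DoF). Every joint is
decomposed internally into elementary prismatic/revolute degrees of freedom,
which makes the position/velocity/acceleration recursion uniform and exact.

Conventions: ground frame is y-up, x is the walking direction, z lateral.
Angles are radians, lengths metres, masses kilograms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

GRAVITY = np.array([0.0, -9.80665, 0.0])

JOINT_NDOF = {"revolute": 1, "free_planar": 3, "free_spatial": 6}


class ModelError(ValueError):
    """Raised for schema violations, cyclic trees or dangling references."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RigidSegment:
    """A rigid body: mass, inertia about its COM (segment frame) and geometry."""

    name: str
    mass: float
    inertia: np.ndarray           # 3x3, kg m^2, about COM, in segment frame
    com_offset: np.ndarray        # COM position in segment frame
    endpoints: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mass < 0:
            raise ModelError(f"segment {self.name}: negative mass")
        I = np.asarray(self.inertia, float)
        if I.shape != (3, 3) or not np.allclose(I, I.T, atol=1e-12):
            raise ModelError(f"segment {self.name}: inertia must be symmetric 3x3")
        w = np.linalg.eigvalsh(I)
        if w[0] < -1e-12:
            raise ModelError(f"segment {self.name}: inertia not positive semidefinite")
        # principal moments must satisfy the triangle inequality
        if w[0] + w[1] < w[2] - 1e-9 * max(1.0, w[2]):
            raise ModelError(f"segment {self.name}: principal moments violate triangle inequality")


@dataclass
class JointDef:
    name: str
    type: str                     # revolute | free_planar | free_spatial
    parent: str                   # parent segment name or "ground"
    child: str
    offset_parent: np.ndarray     # joint anchor in parent frame
    offset_child: np.ndarray      # joint anchor in child frame
    axes: np.ndarray              # (k, 3) axis list; revolute: 1 axis
    coordinates: list[str] = field(default_factory=list)

    @property
    def ndof(self) -> int:
        return JOINT_NDOF[self.type]

    def elementary(self) -> list[tuple[str, np.ndarray]]:
        """Decompose into ordered elementary (kind, local axis) DoFs."""
        ax = np.asarray(self.axes, float).reshape(-1, 3)
        if self.type == "revolute":
            return [("rev", ax[0])]
        if self.type == "free_planar":
            # two translations in the plane, then a rotation about the normal
            return [("pris", ax[0]), ("pris", ax[1]), ("rev", ax[2])]
        if self.type == "free_spatial":
            e = np.eye(3)
            return [("pris", e[0]), ("pris", e[1]), ("pris", e[2]),
                    ("rev", e[0]), ("rev", e[1]), ("rev", e[2])]
        raise ModelError(f"joint {self.name}: unknown type {self.type!r}")


@dataclass
class MarkerDef:
    name: str
    segment: str
    local_position: np.ndarray


@dataclass
class ImuDef:
    name: str
    segment: str
    local_orientation: Rotation   # sensor-to-segment


@dataclass
class MuscleDef:
    """Straight-line (via-point) muscle path with a maximum isometric force."""

    name: str
    fmax: float
    path: list[tuple[str, np.ndarray]]   # ordered (segment, local point)

    def validate(self) -> None:
        if self.fmax <= 0:
            raise ModelError(f"muscle {self.name}: fmax must be > 0")
        if len(self.path) < 2 or len({seg for seg, _ in self.path}) < 2:
            raise ModelError(f"muscle {self.name}: path needs >= 2 points on >= 2 segments")


@dataclass
class GenState:
    """Generalized coordinates and their first/second derivatives at time t."""

    t: float
    q: np.ndarray
    u: np.ndarray
    a: np.ndarray

    def validate(self, n: int) -> None:
        for name, v in (("q", self.q), ("u", self.u), ("a", self.a)):
            v = np.asarray(v, float)
            if v.shape != (n,):
                raise ModelError(f"GenState.{name}: expected shape ({n},), got {v.shape}")
            if not np.all(np.isfinite(v)):
                raise ModelError(f"GenState.{name}: non-finite entries")


@dataclass
class SegmentKinematics:
    """Full spatial kinematics of one segment, all in the ground frame."""

    rotation: Rotation
    origin: np.ndarray
    com: np.ndarray
    com_velocity: np.ndarray
    com_acceleration: np.ndarray
    angular_velocity: np.ndarray
    angular_acceleration: np.ndarray
    origin_velocity: np.ndarray
    origin_acceleration: np.ndarray


@dataclass
class DofInfo:
    """Geometry of one elementary DoF at a given configuration (world frame)."""

    kind: str                 # "pris" | "rev"
    axis: np.ndarray          # world axis
    point: np.ndarray         # rotation centre (rev) / anchor (pris)
    joint: str
    coordinate: str
    child_segment: str


SpatialKinematics = dict[str, SegmentKinematics]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class Model:
    """Validated rigid-body tree with markers, IMUs and muscles."""

    def __init__(self, segments: Sequence[RigidSegment], joints: Sequence[JointDef],
                 markers: Sequence[MarkerDef] = (), imus: Sequence[ImuDef] = (),
                 muscles: Sequence[MuscleDef] = (), name: str = "model"):
        self.name = name
        self.segments: dict[str, RigidSegment] = {}
        for seg in segments:
            if seg.name in self.segments or seg.name == "ground":
                raise ModelError(f"duplicate or reserved segment name {seg.name!r}")
            seg.validate()
            self.segments[seg.name] = seg
        self.joints = self._order_joints(list(joints))
        self.markers = {m.name: m for m in markers}
        self.imus = {s.name: s for s in imus}
        self.muscles = {m.name: m for m in muscles}
        for m in markers:
            if m.segment not in self.segments:
                raise ModelError(f"marker {m.name}: unknown segment {m.segment!r}")
        for s in imus:
            if s.segment not in self.segments:
                raise ModelError(f"imu {s.name}: unknown segment {s.segment!r}")
        for mu in muscles:
            mu.validate()
            for seg, _ in mu.path:
                if seg not in self.segments:
                    raise ModelError(f"muscle {mu.name}: unknown segment {seg!r}")
        self.coordinate_names: list[str] = []
        for j in self.joints:
            if len(j.coordinates) != j.ndof:
                raise ModelError(f"joint {j.name}: expected {j.ndof} coordinate names")
            self.coordinate_names.extend(j.coordinates)
        self.n_coordinates = len(self.coordinate_names)
        self.n_base = self.joints[0].ndof if self.joints and self.joints[0].parent == "ground" else 0
        # children lookup for subtree queries
        self._children: dict[str, list[str]] = {}
        for j in self.joints:
            self._children.setdefault(j.parent, []).append(j.child)
        # coordinate indices affecting each segment (ancestors' DoFs)
        self._coords_of: dict[str, list[int]] = {}
        iq = 0
        for j in self.joints:
            own = list(range(iq, iq + j.ndof))
            iq += j.ndof
            inherited = self._coords_of.get(j.parent, [])
            self._coords_of[j.child] = inherited + own

    def _order_joints(self, joints: list[JointDef]) -> list[JointDef]:
        """Deterministic depth-first ordering from the ground, base joint first."""
        by_child: dict[str, JointDef] = {}
        for j in joints:
            if j.child in by_child:
                raise ModelError(f"segment {j.child!r} has two parent joints")
            if j.child not in self.segments:
                raise ModelError(f"joint {j.name}: unknown child segment {j.child!r}")
            if j.parent != "ground" and j.parent not in self.segments:
                raise ModelError(f"joint {j.name}: unknown parent segment {j.parent!r}")
            by_child[j.child] = j
        children: dict[str, list[JointDef]] = {}
        for j in joints:
            children.setdefault(j.parent, []).append(j)
        ordered: list[JointDef] = []
        stack = list(reversed(children.get("ground", [])))
        seen: set[str] = set()
        while stack:
            j = stack.pop()
            if j.child in seen:
                raise ModelError("cyclic joint tree")
            seen.add(j.child)
            ordered.append(j)
            stack.extend(reversed(children.get(j.child, [])))
        if len(ordered) != len(joints):
            raise ModelError("joint graph is not a tree rooted at ground "
                             "(cycle or disconnected segment)")
        if set(by_child) != set(self.segments):
            orphans = set(self.segments) - set(by_child)
            raise ModelError(f"segments without a parent joint: {sorted(orphans)}")
        return ordered

    # -- queries ------------------------------------------------------------

    def coordinate_index(self, name: str) -> int:
        return self.coordinate_names.index(name)

    def coordinates_affecting(self, segment: str) -> list[int]:
        """Indices of the coordinates on the path from the ground to the
        segment (the only ones its kinematics depend on)."""
        return self._coords_of[segment]

    def subtree(self, segment: str) -> list[str]:
        """Segment and all its descendants, in tree order."""
        out, stack = [], [segment]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(reversed(self._children.get(s, [])))
        return out

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def default_state(self, t: float = 0.0) -> GenState:
        n = self.n_coordinates
        return GenState(t, np.zeros(n), np.zeros(n), np.zeros(n))


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _vec(x, name: str) -> np.ndarray:
    v = np.asarray(x, float)
    if v.shape != (3,):
        raise ModelError(f"{name}: expected a 3-vector, got {x!r}")
    return v


def _inertia_from_list(vals, name: str) -> np.ndarray:
    v = list(vals)
    if len(v) != 6:
        raise ModelError(f"{name}: inertia must be [xx, yy, zz, xy, xz, yz]")
    xx, yy, zz, xy, xz, yz = (float(c) for c in v)
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def load_model(path: str | Path) -> Model:
    """Load and validate a model description file (YAML or JSON).

    Top-level keys: ``segments``, ``joints`` and optionally ``markers``,
    ``imus``, ``muscles``. See the bundled ``pendulum.yaml`` and
    ``planar_walker.yaml`` for the schema.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "segments" not in doc or "joints" not in doc:
        raise ModelError(f"{path}: model file needs 'segments' and 'joints'")
    return model_from_dict(doc, name=doc.get("name", path.stem))


def model_from_dict(doc: Mapping, name: str = "model") -> Model:
    segments = []
    for s in doc["segments"]:
        segments.append(RigidSegment(
            name=s["name"], mass=float(s["mass"]),
            inertia=_inertia_from_list(s["inertia"], s["name"]),
            com_offset=_vec(s.get("com", [0, 0, 0]), f"{s['name']}.com"),
            endpoints={k: _vec(v, f"{s['name']}.endpoints.{k}")
                       for k, v in (s.get("endpoints") or {}).items()},
        ))
    joints = []
    for j in doc["joints"]:
        jtype = j["type"]
        if jtype not in JOINT_NDOF:
            raise ModelError(f"joint {j['name']}: unknown type {jtype!r}")
        default_axes = {"revolute": [[0, 0, 1]],
                        "free_planar": [[1, 0, 0], [0, 1, 0], [0, 0, 1]],
                        "free_spatial": np.eye(3).tolist()}[jtype]
        axes = np.asarray(j.get("axes", default_axes), float).reshape(-1, 3)
        coords = j.get("coordinates")
        if coords is None:
            ndof = JOINT_NDOF[jtype]
            coords = [j["name"]] if ndof == 1 else [f"{j['name']}_{i}" for i in range(ndof)]
        joints.append(JointDef(
            name=j["name"], type=jtype, parent=j["parent"], child=j["child"],
            offset_parent=_vec(j.get("offset_parent", [0, 0, 0]), f"{j['name']}.offset_parent"),
            offset_child=_vec(j.get("offset_child", [0, 0, 0]), f"{j['name']}.offset_child"),
            axes=axes, coordinates=list(coords)))
    markers = [MarkerDef(m["name"], m["segment"], _vec(m["position"], m["name"]))
               for m in doc.get("markers") or []]
    imus = []
    for s in doc.get("imus") or []:
        rot = s.get("orientation")
        r = Rotation.identity() if rot is None else Rotation.from_quat(
            [rot[1], rot[2], rot[3], rot[0]])  # file stores w,x,y,z
        imus.append(ImuDef(s["name"], s["segment"], r))
    muscles = [MuscleDef(m["name"], float(m["fmax"]),
                         [(seg, _vec(p, m["name"])) for seg, p in
                          ((pt[0], pt[1:4]) if len(pt) == 4 else (pt[0], pt[1])
                           for pt in m["path"])])
               for m in doc.get("muscles") or []]
    return Model(segments, joints, markers, imus, muscles, name=name)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _rot(axis: np.ndarray, angle: float) -> Rotation:
    return Rotation.from_rotvec(np.asarray(axis, float) * angle)


def tree_kinematics(model: Model, q: np.ndarray,
                    u: np.ndarray | None = None,
                    a: np.ndarray | None = None,
                    ) -> tuple[SpatialKinematics, list[DofInfo]]:
    """One forward pass over the tree.

    Propagates positions and, when ``u``/``a`` are given, velocities and
    accelerations through every elementary DoF. Also returns per-DoF world
    geometry (axis, anchor point) used for Jacobian-transpose projections.
    """
    q = np.asarray(q, float)
    if q.shape != (model.n_coordinates,):
        raise ModelError(f"expected q of shape ({model.n_coordinates},), got {q.shape}")
    zero = np.zeros(3)
    u = np.zeros_like(q) if u is None else np.asarray(u, float)
    a = np.zeros_like(q) if a is None else np.asarray(a, float)

    kin: SpatialKinematics = {}
    dofs: list[DofInfo] = []
    iq = 0
    for joint in model.joints:
        if joint.parent == "ground":
            R, p = Rotation.identity(), zero
            w = al = vp = ap = zero
        else:
            pk = kin[joint.parent]
            R, p = pk.rotation, pk.origin
            w, al, vp, ap = (pk.angular_velocity, pk.angular_acceleration,
                             pk.origin_velocity, pk.origin_acceleration)

        def attach(d_local, Rf, pos, vel, acc, w_, al_):
            dw = Rf.apply(d_local)
            return (pos + dw,
                    vel + np.cross(w_, dw),
                    acc + np.cross(al_, dw) + np.cross(w_, np.cross(w_, dw)))

        x, vx, ax = attach(joint.offset_parent, R, p, vp, ap, w, al)

        for (kind, axis), coord in zip(joint.elementary(), joint.coordinates):
            qi, ui, ai = q[iq], u[iq], a[iq]
            wax = R.apply(axis)
            if kind == "pris":
                dw = wax * qi
                ax = ax + np.cross(al, dw) + np.cross(w, np.cross(w, dw)) \
                    + 2.0 * np.cross(w, wax * ui) + wax * ai
                vx = vx + np.cross(w, dw) + wax * ui
                x = x + dw
                dofs.append(DofInfo("pris", wax, x.copy(), joint.name, coord, joint.child))
            else:
                dofs.append(DofInfo("rev", wax, x.copy(), joint.name, coord, joint.child))
                al = al + np.cross(w, wax * ui) + wax * ai
                w = w + wax * ui
                R = R * _rot(axis, qi)
            iq += 1

        pc, vc, ac = attach(-joint.offset_child, R, x, vx, ax, w, al)
        seg = model.segments[joint.child]
        cw = R.apply(seg.com_offset)
        kin[joint.child] = SegmentKinematics(
            rotation=R, origin=pc,
            com=pc + cw,
            com_velocity=vc + np.cross(w, cw),
            com_acceleration=ac + np.cross(al, cw) + np.cross(w, np.cross(w, cw)),
            angular_velocity=w, angular_acceleration=al,
            origin_velocity=vc, origin_acceleration=ac)
    return kin, dofs


@dataclass
class FKResult:
    segments: SpatialKinematics
    markers: dict[str, np.ndarray]
    imus: dict[str, Rotation]

    def segment_point(self, model: Model, segment: str, local: np.ndarray) -> np.ndarray:
        k = self.segments[segment]
        return k.origin + k.rotation.apply(local)


def forward_kinematics(model: Model, q: np.ndarray) -> FKResult:
    """Segment transforms, marker world positions and IMU world orientations."""
    kin, _ = tree_kinematics(model, q)
    markers = {m.name: kin[m.segment].origin + kin[m.segment].rotation.apply(m.local_position)
               for m in model.markers.values()}
    imus = {s.name: kin[s.segment].rotation * s.local_orientation
            for s in model.imus.values()}
    return FKResult(kin, markers, imus)


def com_kinematics(model: Model, state: GenState) -> SpatialKinematics:
    """COM positions/velocities/accelerations and angular rates per segment."""
    state.validate(model.n_coordinates)
    kin, _ = tree_kinematics(model, state.q, state.u, state.a)
    return kin


def endpoint_world(model: Model, kin: SpatialKinematics, segment: str, endpoint: str) -> np.ndarray:
    seg = model.segments[segment]
    if endpoint not in seg.endpoints:
        raise ModelError(f"segment {segment} has no endpoint {endpoint!r}")
    k = kin[segment]
    return k.origin + k.rotation.apply(seg.endpoints[endpoint])
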