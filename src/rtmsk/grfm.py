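"""Ground reaction force & moment (GRF&M) prediction from kinematics alone.

The total external wrench follows from the Newton-Euler equations of motion
summed over all segments (the GRF&M being the only external load during
gait). During single support the stance limb carries the whole wrench; during
double support the indeterminacy is resolved by the smooth transition
assumption: in a walking-direction frame the trailing leg's wrench decays
from its value cached at the leading leg's heel-strike to zero over the
double-support period via a monotone transition function, and the leading leg
takes the remainder. Gait phases come from a debounced threshold state
machine; the centre of pressure travels from heel to metatarsophalangeal
joint following a closed-form scaling of the stance frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .dynamics import ExternalWrench
from .model import GRAVITY, GenState, Model, ModelError, SpatialKinematics, com_kinematics

VERTICAL = np.array([0.0, 1.0, 0.0])
ANTERIOR = np.array([1.0, 0.0, 0.0])
LEGS = ("r", "l")


# ---------------------------------------------------------------------------
# total wrench
# ---------------------------------------------------------------------------

def total_wrench(model: Model, spatial: SpatialKinematics,
                 gravity: np.ndarray = GRAVITY) -> tuple[np.ndarray, np.ndarray]:
    """Total external force and moment (about the ground origin) implied by
    the segment kinematics: f = sum m_i (a_i - g); tau = sum [I_i w'_i +
    w_i x I_i w_i] + sum c_i x m_i (a_i - g)."""
    f_total = np.zeros(3)
    tau_total = np.zeros(3)
    for name, seg in model.segments.items():
        k = spatial[name]
        R = k.rotation.as_matrix()
        Iw = R @ seg.inertia @ R.T
        fi = seg.mass * (k.com_acceleration - gravity)
        f_total += fi
        tau_total += Iw @ k.angular_acceleration \
            + np.cross(k.angular_velocity, Iw @ k.angular_velocity) \
            + np.cross(k.com, fi)
    return f_total, tau_total


# ---------------------------------------------------------------------------
# gait phase state machine
# ---------------------------------------------------------------------------

@dataclass
class GaitEvents:
    heel_strikes: dict[str, list[float]] = field(default_factory=lambda: {l: [] for l in LEGS})
    toe_offs: dict[str, list[float]] = field(default_factory=lambda: {l: [] for l in LEGS})


@dataclass
class GaitPhaseState:
    """Committed per-leg phase plus event log and period estimates."""

    phase: dict[str, str] = field(default_factory=lambda: {l: "stance" for l in LEGS})
    leading_leg: str | None = None
    events: GaitEvents = field(default_factory=GaitEvents)
    T_ds: float | None = None
    T_ss: float | None = None


class LegPhaseDetector:
    """Debounced threshold detector for one leg.

    Raw detection is ``stance`` when the measure u(t) >= v_th, ``swing``
    otherwise. The committed phase flips only after k consecutive raw
    detections of the opposite phase; the emitted event is timestamped at the
    first sample of the committing run.
    """

    def __init__(self, v_th: float, k: int = 3):
        if k < 1:
            raise ModelError("debounce count k must be >= 1")
        self.v_th = v_th
        self.k = k
        self.committed: str | None = None
        self._run: list[float] = []      # timestamps of the current opposite-run

    def update(self, t: float, u: float) -> tuple[str, tuple[str, float] | None]:
        """Returns (committed phase, event) where event is ('heel_strike'|
        'toe_off', time) when the phase flips."""
        raw = "stance" if u >= self.v_th else "swing"
        if self.committed is None:
            self.committed = raw
            return self.committed, None
        if raw == self.committed:
            self._run.clear()
            return self.committed, None
        self._run.append(t)
        if len(self._run) >= self.k:
            t_event = self._run[0]
            self.committed = raw
            self._run.clear()
            kind = "heel_strike" if raw == "stance" else "toe_off"
            return self.committed, (kind, t_event)
        return self.committed, None


def detect_gait_phase(times: Sequence[float], u: Sequence[float], v_th: float,
                      k: int = 3) -> tuple[list[str], GaitEvents]:
    """Run the debounced detector over a single-leg measure stream (helper for
    tests and offline use); returns the committed phase per sample and the
    emitted events (logged under leg 'r')."""
    det = LegPhaseDetector(v_th, k)
    phases, events = [], GaitEvents()
    for t, ui in zip(times, u):
        ph, ev = det.update(float(t), float(ui))
        phases.append(ph)
        if ev:
            kind, te = ev
            (events.heel_strikes if kind == "heel_strike" else events.toe_offs)["r"].append(te)
    return phases, events


# ---------------------------------------------------------------------------
# walking direction
# ---------------------------------------------------------------------------

def walking_direction(pelvis_orientations: Sequence[Rotation]) -> Rotation:
    """Heading rotation about the vertical from the circular-mean yaw of the
    pelvis anterior axis's horizontal projection."""
    if len(pelvis_orientations) == 0:
        raise ModelError("need at least one pelvis orientation sample")
    sines, cosines = 0.0, 0.0
    for rot in pelvis_orientations:
        ant = rot.apply(ANTERIOR)
        h = ant - (ant @ VERTICAL) * VERTICAL
        n = np.linalg.norm(h)
        if n < 1e-9:
            raise ModelError("pelvis anterior axis near vertical; heading undefined")
        h /= n
        yaw = np.arctan2(-h[2], h[0])   # rotation about +y maps x to (cos, 0, -sin)
        sines += np.sin(yaw)
        cosines += np.cos(yaw)
    psi = np.arctan2(sines, cosines)
    return Rotation.from_rotvec(psi * VERTICAL)


# ---------------------------------------------------------------------------
# transition function and CoP model
# ---------------------------------------------------------------------------

@dataclass
class TransitionFunction:
    """Monotone non-increasing map of normalized double-support time s in
    [0, 1] to per-component multipliers in [0, 1]^3 (force and moment).

    ``smoothstep`` is 1 - (3 s^2 - 2 s^3); ``linear`` is 1 - s; ``custom``
    interpolates user tables per component so that per-component shapes can be
    configured."""

    shape: str = "smoothstep"
    force_table: np.ndarray | None = None    # (npts, 1+3): s, fx, fy, fz
    moment_table: np.ndarray | None = None

    def _scalar(self, s: float) -> float:
        if self.shape == "smoothstep":
            return 1.0 - (3.0 * s ** 2 - 2.0 * s ** 3)
        if self.shape == "linear":
            return 1.0 - s
        raise ModelError(f"unknown transition shape {self.shape!r}")

    def _eval(self, s: float, table: np.ndarray | None) -> np.ndarray:
        s = float(np.clip(s, 0.0, 1.0))
        if self.shape == "custom":
            if table is None:
                raise ModelError("custom transition requires a table")
            tab = np.asarray(table, float)
            return np.array([np.interp(s, tab[:, 0], tab[:, 1 + i]) for i in range(3)])
        return np.full(3, self._scalar(s))

    def force(self, s: float) -> np.ndarray:
        return self._eval(s, self.force_table)

    def moment(self, s: float) -> np.ndarray:
        return self._eval(s, self.moment_table)


def cop_scaling(t_in_stance: float, T_ss: float) -> float:
    """Heel-to-metatarsophalangeal CoP progression factor during single
    support: sigma(t) = -(2/(3 pi)) [sin(wt) - sin(2wt)/8 - (3/4) wt] with
    stance frequency w = 2 pi / T_ss; sigma(0) = 0, sigma(T_ss) = 1."""
    if T_ss <= 0:
        raise ModelError("T_ss must be positive")
    wt = 2.0 * np.pi * t_in_stance / T_ss
    return float(-(2.0 / (3.0 * np.pi)) * (np.sin(wt) - np.sin(2.0 * wt) / 8.0 - 0.75 * wt))


def cop_trajectory(model: Model, kin: SpatialKinematics, foot_segment: str,
                   sigma: float) -> np.ndarray:
    """CoP point: ground-plane projection of heel + sigma * (heel->mtp)."""
    seg = model.segments[foot_segment]
    if "heel" not in seg.endpoints or "mtp" not in seg.endpoints:
        raise ModelError(f"{foot_segment} needs 'heel' and 'mtp' endpoints")
    k = kin[foot_segment]
    heel = k.origin + k.rotation.apply(seg.endpoints["heel"])
    mtp = k.origin + k.rotation.apply(seg.endpoints["mtp"])
    p = heel + sigma * (mtp - heel)
    p[1] = 0.0
    return p


# ---------------------------------------------------------------------------
# distribution engine
# ---------------------------------------------------------------------------

@dataclass
class GrfmConfig:
    """Configuration of the predictor and of the distribution engine."""

    foot_segments: dict[str, str] = field(
        default_factory=lambda: {"r": "foot_r", "l": "foot_l"})
    pelvis_segment: str = "pelvis"
    height_threshold: float = 0.02   # m: stance when the heel is below this
    debounce: int = 3
    transition: TransitionFunction = field(default_factory=TransitionFunction)
    T_ds_default: float = 0.11       # s, used until an estimate is available
    T_ss_default: float = 0.44
    # optional external contact measure: (leg, index, t) -> u value, with
    # stance committed when u >= contact_threshold (e.g. insole signal)
    contact_measure: Callable[[str, int, float], float] | None = None
    contact_threshold: float = 0.5


@dataclass
class GrfmResult:
    times: np.ndarray
    wrenches: dict[str, list[ExternalWrench]]
    total_force: np.ndarray         # (n, 3) ground frame, about origin
    total_moment: np.ndarray
    events: GaitEvents
    state: GaitPhaseState
    heading: Rotation


class WrenchDistributor:
    """Per-sample smooth-transition split of the total wrench between legs.

    Consumes committed contact flags per leg plus the walking-frame totals and
    produces per-leg walking-frame forces/moments, maintaining the leading-leg
    bookkeeping, the cached heel-strike totals and the running double/single
    support period estimates.
    """

    def __init__(self, config: GrfmConfig):
        self.cfg = config
        self.state = GaitPhaseState()
        self._cached_f: np.ndarray | None = None
        self._cached_m: np.ndarray | None = None
        self._t_hs: float | None = None
        self._t_ss_start: float | None = None
        self._last_stance: str = "r"

    def _on_heel_strike(self, leg: str, t: float, f_tot: np.ndarray, m_tot: np.ndarray):
        st = self.state
        if self._t_ss_start is not None and t > self._t_ss_start:
            st.T_ss = t - self._t_ss_start
        st.leading_leg = leg
        st.events.heel_strikes[leg].append(t)
        self._t_hs = t
        self._cached_f = f_tot.copy()
        self._cached_m = m_tot.copy()

    def _on_toe_off(self, leg: str, t: float):
        st = self.state
        st.events.toe_offs[leg].append(t)
        if self._t_hs is not None and t > self._t_hs and st.leading_leg != leg:
            st.T_ds = t - self._t_hs
        self._t_ss_start = t

    def step(self, t: float, f_tot_w: np.ndarray, m_tot_w: np.ndarray,
             contact: dict[str, bool],
             events: list[tuple[str, str, float]] = ()) -> dict[str, tuple]:
        """Advance one sample. ``events`` lists (kind, leg, time) emitted by
        the detectors at this sample. Returns per-leg walking-frame
        (force, moment, sigma) tuples; sigma is the CoP progression factor
        (None outside single support)."""
        cfg, st = self.cfg, self.state
        for kind, leg, te in events:
            if kind == "heel_strike":
                self._on_heel_strike(leg, te, f_tot_w, m_tot_w)
            else:
                self._on_toe_off(leg, te)
        st.phase = {l: ("stance" if contact[l] else "swing") for l in LEGS}
        stance = [l for l in LEGS if contact[l]]

        zero = np.zeros(3)
        out: dict[str, tuple] = {}
        if len(stance) == 1:
            leg = stance[0]
            self._last_stance = leg
            sigma = None
            if self._t_ss_start is not None and t >= self._t_ss_start:
                T_ss = st.T_ss or cfg.T_ss_default
                sigma = cop_scaling(min(t - self._t_ss_start, T_ss), T_ss)
            out[leg] = (f_tot_w, m_tot_w, sigma)
            out["l" if leg == "r" else "r"] = (zero, zero, None)
        elif len(stance) == 2:
            leading = st.leading_leg
            if leading is None or self._t_hs is None:
                # before the first heel-strike: single-support fallback on the
                # most recent stance leg (deterministic tie-break)
                leg = self._last_stance
                out[leg] = (f_tot_w, m_tot_w, None)
                out["l" if leg == "r" else "r"] = (zero, zero, None)
            else:
                trailing = "l" if leading == "r" else "r"
                T_ds = st.T_ds or cfg.T_ds_default
                s = (t - self._t_hs) / T_ds
                f_trail = self._cached_f * cfg.transition.force(s)
                m_trail = self._cached_m * cfg.transition.moment(s)
                out[trailing] = (f_trail, m_trail, None)
                out[leading] = (f_tot_w - f_trail, m_tot_w - m_trail, None)
        else:
            # flight is outside the walking model; keep conservation by
            # assigning the total to the last stance leg
            leg = self._last_stance
            out[leg] = (f_tot_w, m_tot_w, None)
            out["l" if leg == "r" else "r"] = (zero, zero, None)
        return out


def distribute_wrench(f_total_w: np.ndarray, m_total_w: np.ndarray,
                      state: GaitPhaseState, transition: TransitionFunction,
                      t: float, t_hs: float, cached_f: np.ndarray,
                      cached_m: np.ndarray, T_ds: float
                      ) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stateless double-support split (leading, trailing) in the walking
    frame: trailing = cached-at-heel-strike (element-wise) transition(t - t_hs),
    leading = total - trailing."""
    s = (t - t_hs) / T_ds
    f_trail = np.asarray(cached_f, float) * transition.force(s)
    m_trail = np.asarray(cached_m, float) * transition.moment(s)
    return (f_total_w - f_trail, m_total_w - m_trail), (f_trail, m_trail)


# ---------------------------------------------------------------------------
# full prediction
# ---------------------------------------------------------------------------

def _heel_height(model: Model, kin: SpatialKinematics, foot: str) -> float:
    seg = model.segments[foot]
    k = kin[foot]
    return float((k.origin + k.rotation.apply(seg.endpoints["heel"]))[1])


def predict_grfm(model: Model, states: Sequence[GenState],
                 config: GrfmConfig | None = None) -> GrfmResult:
    """Predict per-leg ground reaction wrenches from a filtered kinematics
    stream: total wrench -> walking-frame transform -> phase detection ->
    smooth-transition distribution -> per-leg CoP -> ground-frame wrenches
    with moments re-expressed about the assigned CoP."""
    cfg = config or GrfmConfig()
    n = len(states)
    if n == 0:
        raise ModelError("empty state stream")
    kins = [com_kinematics(model, st) for st in states]
    times = np.array([st.t for st in states])

    totals = [total_wrench(model, k) for k in kins]
    f_tot = np.array([f for f, _ in totals])
    m_tot = np.array([m for _, m in totals])

    heading = walking_direction([k[cfg.pelvis_segment].rotation for k in kins])
    Rw = heading.inv()      # ground -> walking frame
    f_tot_w = Rw.apply(f_tot)
    m_tot_w = Rw.apply(m_tot)

    detectors = {}
    for leg in LEGS:
        if cfg.contact_measure is None:
            detectors[leg] = LegPhaseDetector(-cfg.height_threshold, cfg.debounce)
        else:
            detectors[leg] = LegPhaseDetector(cfg.contact_threshold, cfg.debounce)

    dist = WrenchDistributor(cfg)
    wrenches: dict[str, list[ExternalWrench]] = {l: [] for l in LEGS}
    for i in range(n):
        t = float(times[i])
        contact, events = {}, []
        for leg in LEGS:
            if cfg.contact_measure is None:
                u = -_heel_height(model, kins[i], cfg.foot_segments[leg])
            else:
                u = cfg.contact_measure(leg, i, t)
            ph, ev = detectors[leg].update(t, u)
            contact[leg] = ph == "stance"
            if ev:
                events.append((ev[0], leg, ev[1]))
        split = dist.step(t, f_tot_w[i], m_tot_w[i], contact, events)
        for leg in LEGS:
            fw, mw, sigma = split[leg]
            fg = heading.apply(fw)
            mg = heading.apply(mw)
            if not contact[leg] or np.allclose(fg, 0.0):
                cop = cop_trajectory(model, kins[i], cfg.foot_segments[leg], 0.0)
            elif sigma is not None:
                cop = cop_trajectory(model, kins[i], cfg.foot_segments[leg], sigma)
            elif dist.state.leading_leg == leg or dist.state.leading_leg is None:
                cop = cop_trajectory(model, kins[i], cfg.foot_segments[leg], 0.0)
            else:
                cop = cop_trajectory(model, kins[i], cfg.foot_segments[leg], 1.0)
            wrenches[leg].append(ExternalWrench(
                point=cop, force=fg, moment=mg - np.cross(cop, fg), frame="ground"))
    return GrfmResult(times, wrenches, f_tot, m_tot, dist.state.events,
                      dist.state, heading)
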