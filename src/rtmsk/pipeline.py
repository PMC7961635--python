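"""End-to-end pipeline: acquisition (IK) and processing threads.

The acquisition loop solves IK per arriving observation frame and pushes the
generalized coordinates into a thread-safe buffer; the processing loop
consumes them through the real-time filter, inverse dynamics with predicted
(or measured) ground reaction wrenches, muscle optimization and joint
reaction analysis. A single-threaded ``replay`` mode executes the identical
per-frame operations in order and produces value-identical outputs (the
threaded mode uses the blocking buffer policy by default for the same
determinism guarantee).
"""

from __future__ import annotations

import threading
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import ExternalWrench, recursive_newton_euler
from .grfm import (GrfmConfig, LegPhaseDetector, WrenchDistributor, cop_trajectory,
                   total_wrench, walking_direction)
from .ik import MarkerHistory, ObservationFrame, complete_markers, solve_frame
from .io import FrameBuffer, LatencyLog
from .model import GenState, Model, ModelError, com_kinematics
from .muscles import MomentArmModel, build_moment_arm_model, solve_frame as solve_muscles
from .reactions import joint_reaction_analysis
from .rtfilter import WARMING_UP, FilterConfig, RealTimeFilter


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    grfm: GrfmConfig | None = field(default_factory=GrfmConfig)
    measured_wrenches: dict[str, list[ExternalWrench]] | None = None
    wrench_segments: dict[str, str] | None = None
    solve_muscle_forces: bool = True
    muscle_p: int = 2
    arm_model: MomentArmModel | None = None
    complete_markers: bool = True
    buffer_capacity: int = 256
    overflow: str = "block"
    q0: np.ndarray | None = None


class StreamingGrfmPredictor:
    """Per-frame GRF&M prediction (streaming counterpart of
    :func:`rtmsk.grfm.predict_grfm`): running circular-mean heading, debounced
    per-leg phase detection and smooth-transition distribution."""

    def __init__(self, model: Model, config: GrfmConfig):
        self.model = model
        self.cfg = config
        self._sin = 0.0
        self._cos = 0.0
        self.detectors = {}
        for leg in ("r", "l"):
            if config.contact_measure is None:
                self.detectors[leg] = LegPhaseDetector(-config.height_threshold,
                                                       config.debounce)
            else:
                self.detectors[leg] = LegPhaseDetector(config.contact_threshold,
                                                       config.debounce)
        self.distributor = WrenchDistributor(config)

    def step(self, index: int, state: GenState, kin) -> dict[str, ExternalWrench]:
        from scipy.spatial.transform import Rotation

        model, cfg = self.model, self.cfg
        ant = kin[cfg.pelvis_segment].rotation.apply(np.array([1.0, 0.0, 0.0]))
        h = ant - ant[1] * np.array([0.0, 1.0, 0.0])
        n = np.linalg.norm(h)
        if n > 1e-9:
            yaw = np.arctan2(-h[2], h[0])
            self._sin += np.sin(yaw)
            self._cos += np.cos(yaw)
        psi = np.arctan2(self._sin, self._cos) if (self._sin, self._cos) != (0, 0) else 0.0
        heading = Rotation.from_rotvec([0.0, psi, 0.0])

        f_tot, m_tot = total_wrench(model, kin)
        fw = heading.inv().apply(f_tot)
        mw = heading.inv().apply(m_tot)

        t = state.t
        contact, events = {}, []
        for leg in ("r", "l"):
            if cfg.contact_measure is None:
                seg = model.segments[cfg.foot_segments[leg]]
                k = kin[cfg.foot_segments[leg]]
                u = -float((k.origin + k.rotation.apply(seg.endpoints["heel"]))[1])
            else:
                u = cfg.contact_measure(leg, index, t)
            ph, ev = self.detectors[leg].update(t, u)
            contact[leg] = ph == "stance"
            if ev:
                events.append((ev[0], leg, ev[1]))
        split = self.distributor.step(t, fw, mw, contact, events)
        out = {}
        for leg in ("r", "l"):
            fv, mv, sigma = split[leg]
            fg = heading.apply(fv)
            mg = heading.apply(mv)
            if not contact[leg] or np.allclose(fg, 0.0):
                s = 0.0
            elif sigma is not None:
                s = sigma
            elif self.distributor.state.leading_leg in (leg, None):
                s = 0.0
            else:
                s = 1.0
            cop = cop_trajectory(model, kin, cfg.foot_segments[leg], s)
            out[leg] = ExternalWrench(point=cop, force=fg,
                                      moment=mg - np.cross(cop, fg), frame="ground")
        return out


@dataclass
class PipelineResult:
    coordinates: pd.DataFrame          # raw IK output per frame
    filtered: pd.DataFrame             # value/velocity/acceleration at t_d
    generalized_forces: pd.DataFrame
    grf: pd.DataFrame | None
    muscle_forces: pd.DataFrame | None
    reactions: pd.DataFrame
    latency: LatencyLog
    dropped_frames: int


def _acquire(model: Model, frames, config: PipelineConfig, buffer: FrameBuffer,
             latency: LatencyLog, q_rows: list):
    history = MarkerHistory()
    q = config.q0 if config.q0 is not None else np.zeros(model.n_coordinates)
    for frame in frames:
        with latency.timed("ik"):
            if config.complete_markers and frame.markers:
                frame, _ = complete_markers(frame, model, history)
            res = solve_frame(model, frame, q)
            q = res.q
        q_rows.append((frame.t, q.copy()))
        buffer.put((frame.t, q.copy()))
    buffer.close()


def run_pipeline(model: Model, frames: list[ObservationFrame],
                 config: PipelineConfig | None = None,
                 replay: bool = False) -> PipelineResult:
    """Run the full analysis chain over an observation stream.

    ``replay=True`` executes acquisition and processing sequentially in one
    thread; otherwise the acquisition runs on its own thread and shares
    frames through the buffer. Both modes yield value-identical outputs.
    """
    config = config or PipelineConfig()
    if not frames:
        raise ModelError("no input frames")
    latency = LatencyLog()
    buffer = FrameBuffer(config.buffer_capacity,
                         "block" if replay else config.overflow)
    q_rows: list = []

    if replay:
        _acquire(model, frames, config, buffer, latency, q_rows)
        producer = None
    else:
        producer = threading.Thread(
            target=_acquire, args=(model, frames, config, buffer, latency, q_rows),
            daemon=True)
        producer.start()

    filt = RealTimeFilter(config.filter, model.n_coordinates)
    grfm_stream = (StreamingGrfmPredictor(model, config.grfm)
                   if config.grfm is not None and config.measured_wrenches is None
                   else None)
    arm_model = config.arm_model
    if config.solve_muscle_forces and model.muscles and arm_model is None:
        arm_model = build_moment_arm_model(model)
    muscle_names = list(model.muscles)
    fmax_warm = None

    coord_names = model.coordinate_names
    filt_rows, tau_rows, grf_rows, mus_rows, reac_rows = [], [], [], [], []
    out_index = 0
    for t, q in buffer:
        with latency.timed("filter"):
            out = filt.push_and_evaluate(t, q)
        if out is WARMING_UP:
            continue
        state = GenState(out.t_d, out.value, out.velocity, out.acceleration)
        kin = com_kinematics(model, state)

        external = []
        grf_row = None
        if grfm_stream is not None:
            with latency.timed("grfm"):
                wrenches = grfm_stream.step(out_index, state, kin)
            segs = config.wrench_segments or config.grfm.foot_segments
            external = [(segs[leg], w) for leg, w in wrenches.items()]
            grf_row = [state.t]
            for leg in ("r", "l"):
                w = wrenches[leg]
                grf_row.extend([*w.force, *w.point, *w.moment])
        elif config.measured_wrenches is not None:
            segs = config.wrench_segments or {"r": "foot_r", "l": "foot_l"}
            external = [(segs[leg], ws[out_index])
                        for leg, ws in config.measured_wrenches.items()]

        with latency.timed("id"):
            gf = recursive_newton_euler(model, state, external=external)
        tau_rows.append([state.t, *gf.tau])

        forces = None
        if config.solve_muscle_forces and model.muscles:
            with latency.timed("muscles"):
                mf = solve_muscles(model, arm_model, state.q, gf.actuated,
                                   p=config.muscle_p, warm_start=fmax_warm)
            fmax_warm = mf.forces
            forces = mf.forces
            mus_rows.append([state.t, *forces])

        with latency.timed("reactions"):
            reac = joint_reaction_analysis(model, state, muscle_forces=forces,
                                           external=external,
                                           muscle_names=muscle_names)
        reac_rows.append([state.t] + [v for r in reac for v in (*r.force, *r.moment)])
        filt_rows.append([state.t, *out.value, *out.velocity, *out.acceleration])
        if grf_row is not None:
            grf_rows.append(grf_row)
        out_index += 1

    if producer is not None:
        producer.join()

    def df(rows, cols):
        return pd.DataFrame(rows, columns=cols) if rows else None

    coords = pd.DataFrame([[t, *q] for t, q in q_rows],
                          columns=["time", *coord_names])
    filtered = df(filt_rows, ["time", *coord_names,
                              *(f"{c}_u" for c in coord_names),
                              *(f"{c}_a" for c in coord_names)])
    taus = df(tau_rows, ["time", *coord_names])
    grf_cols = ["time"]
    for leg in ("r", "l"):
        grf_cols += [f"{leg}_ground_force_v{a}" for a in "xyz"]
        grf_cols += [f"{leg}_ground_force_p{a}" for a in "xyz"]
        grf_cols += [f"{leg}_ground_torque_{a}" for a in "xyz"]
    grf = df(grf_rows, grf_cols)
    mus = df(mus_rows, ["time", *muscle_names])
    reac_cols = ["time"]
    for j in model.joints:
        reac_cols += [f"{j.name}_{a}" for a in ("fx", "fy", "fz", "mx", "my", "mz")]
    reactions = df(reac_rows, reac_cols)
    return PipelineResult(coords, filtered, taus, grf, mus, reactions,
                          latency, buffer.dropped)
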