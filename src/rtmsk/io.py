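"""File formats and the acquisition/processing pipeline plumbing.

Readers/writers for the motion-capture ecosystem's tab-delimited formats -
TRC marker trajectories, STO/MOT time-series and quaternion CSV orientation
streams - plus the thread-safe frame buffer and the two-thread (acquisition /
processing) pipeline runner with a deterministic single-threaded replay mode.
"""

from __future__ import annotations

import queue
import threading
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .ik import ObservationFrame
from .model import ModelError


class FileFormatError(ValueError):
    """Malformed header or inconsistent row/column counts."""


# ---------------------------------------------------------------------------
# STO / MOT
# ---------------------------------------------------------------------------

def write_sto(path: str | Path, data: pd.DataFrame, name: str | None = None,
              in_degrees: bool = False) -> None:
    """Write an STO/MOT file; first column must be ``time``."""
    path = Path(path)
    if data.columns[0] != "time":
        raise FileFormatError("first column must be 'time'")
    with open(path, "w") as fh:
        fh.write(f"{name or path.stem}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(data)}\n")
        fh.write(f"nColumns={len(data.columns)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(data.columns) + "\n")
        for _, row in data.iterrows():
            fh.write("\t".join(f"{v:.12g}" for v in row.values) + "\n")


def read_sto(path: str | Path) -> pd.DataFrame:
    """Read an STO/MOT file, validating the header's nRows/nColumns."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip().lower() == "endheader")
    except StopIteration:
        raise FileFormatError(f"{path}: missing 'endheader'")
    for ln in lines[1:end]:
        if "=" in ln:
            k, v = ln.split("=", 1)
            meta[k.strip()] = v.strip()
    body = [ln for ln in lines[end + 1:] if ln.strip()]
    if not body:
        raise FileFormatError(f"{path}: empty body")
    columns = body[0].split("\t")
    rows = [ln.split("\t") for ln in body[1:]]
    if "nRows" in meta and int(meta["nRows"]) != len(rows):
        raise FileFormatError(f"{path}: nRows={meta['nRows']} but body has {len(rows)} rows")
    if "nColumns" in meta and int(meta["nColumns"]) != len(columns):
        raise FileFormatError(
            f"{path}: nColumns={meta['nColumns']} but body has {len(columns)} columns")
    arr = np.array([[float(v) for v in r] for r in rows])
    if arr.shape[1] != len(columns):
        raise FileFormatError(f"{path}: ragged rows")
    return pd.DataFrame(arr, columns=columns)


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def write_trc(path: str | Path, times: np.ndarray,
              markers: dict[str, np.ndarray], data_rate: float,
              units: str = "m") -> None:
    """Write marker trajectories (``markers[name]`` is (n, 3); NaN = missing)."""
    path = Path(path)
    names = list(markers)
    n = len(times)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{data_rate:g}\t{data_rate:g}\t{n}\t{len(names)}\t{units}\t"
                 f"{data_rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\n")
        fh.write("\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}"
                                    for i in range(len(names))) + "\n")
        fh.write("\n")
        for i, t in enumerate(times):
            cells = [str(i + 1), f"{t:.12g}"]
            for name in names:
                xyz = markers[name][i]
                cells.extend("" if np.any(np.isnan(xyz)) else f"{v:.12g}" for v in xyz)
            fh.write("\t".join(cells) + "\n")


def read_trc(path: str | Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a TRC file; missing coordinates come back as NaN."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("PathFileType"):
        raise FileFormatError(f"{path}: not a TRC file (missing PathFileType)")
    counts = lines[2].split("\t")
    n_frames, n_markers = int(counts[2]), int(counts[3])
    names = [c for c in lines[3].split("\t")[2:] if c.strip()]
    if len(names) != n_markers:
        raise FileFormatError(f"{path}: NumMarkers={n_markers} but header names {len(names)}")
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise FileFormatError(f"{path}: NumFrames={n_frames} but {len(data_lines)} data rows")
    times = np.empty(n_frames)
    arrays = {nm: np.full((n_frames, 3), np.nan) for nm in names}
    for i, ln in enumerate(data_lines):
        cells = ln.split("\t")
        times[i] = float(cells[1])
        for m, nm in enumerate(names):
            trip = cells[2 + 3 * m: 5 + 3 * m]
            if len(trip) == 3 and all(c.strip() for c in trip):
                arrays[nm][i] = [float(c) for c in trip]
    return times, arrays


def frames_from_trc(times: np.ndarray, markers: dict[str, np.ndarray]
                    ) -> list[ObservationFrame]:
    out = []
    for i, t in enumerate(times):
        mk = {nm: (None if np.any(np.isnan(arr[i])) else arr[i])
              for nm, arr in markers.items()}
        out.append(ObservationFrame(float(t), markers=mk))
    return out


# ---------------------------------------------------------------------------
# quaternion CSV
# ---------------------------------------------------------------------------

def write_quaternion_csv(path: str | Path, times: np.ndarray,
                         orientations: dict[str, Rotation]) -> None:
    """Columns: time, then <name>_w, <name>_x, <name>_y, <name>_z per sensor."""
    cols = {"time": np.asarray(times, float)}
    for name, rots in orientations.items():
        q = rots.as_quat()            # x, y, z, w
        for j, s in enumerate("xyzw"):
            cols[f"{name}_{s}"] = q[:, j]
    df = pd.DataFrame(cols)
    ordered = ["time"] + [f"{n}_{s}" for n in orientations for s in "wxyz"]
    df[ordered].to_csv(path, index=False)


def read_quaternion_csv(path: str | Path) -> tuple[np.ndarray, dict[str, Rotation]]:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise FileFormatError(f"{path}: missing 'time' column")
    names = sorted({c[:-2] for c in df.columns if c.endswith("_w")})
    out = {}
    for name in names:
        q = np.column_stack([df[f"{name}_{s}"].values for s in "xyzw"])
        out[name] = Rotation.from_quat(q)
    return df["time"].values, out


def frames_from_quaternions(times: np.ndarray, orientations: dict[str, Rotation]
                            ) -> list[ObservationFrame]:
    return [ObservationFrame(float(t), orientations={n: r[i] for n, r in orientations.items()})
            for i, t in enumerate(times)]


# ---------------------------------------------------------------------------
# GRF wrench streams <-> STO layout
# ---------------------------------------------------------------------------

def wrench_stream_to_df(times: np.ndarray, wrenches: dict[str, list]) -> pd.DataFrame:
    """Per-leg wrench streams to the standard GRF table layout
    (``<leg>_ground_force_v*/p*``, ``<leg>_ground_torque_*``)."""
    cols = {"time": np.asarray(times, float)}
    for leg, ws in wrenches.items():
        F = np.array([w.force for w in ws])
        P = np.array([w.point for w in ws])
        M = np.array([w.moment for w in ws])
        for j, a in enumerate("xyz"):
            cols[f"{leg}_ground_force_v{a}"] = F[:, j]
            cols[f"{leg}_ground_force_p{a}"] = P[:, j]
            cols[f"{leg}_ground_torque_{a}"] = M[:, j]
    return pd.DataFrame(cols)


def df_to_wrench_streams(df: pd.DataFrame) -> tuple[np.ndarray, dict[str, list]]:
    from .dynamics import ExternalWrench

    legs = sorted({c.split("_")[0] for c in df.columns if "_ground_force_v" in c})
    out: dict[str, list] = {}
    for leg in legs:
        F = df[[f"{leg}_ground_force_v{a}" for a in "xyz"]].values
        P = df[[f"{leg}_ground_force_p{a}" for a in "xyz"]].values
        M = df[[f"{leg}_ground_torque_{a}" for a in "xyz"]].values
        out[leg] = [ExternalWrench(point=P[i], force=F[i], moment=M[i], frame="ground")
                    for i in range(len(df))]
    return df["time"].values, out


# ---------------------------------------------------------------------------
# frame buffer
# ---------------------------------------------------------------------------

_SENTINEL = object()


class FrameBuffer:
    """Bounded thread-safe FIFO preserving producer order.

    ``overflow='block'`` stalls the producer when full (deterministic);
    ``overflow='drop_oldest'`` discards the oldest pending payload and counts
    the drops (real-time semantics favouring freshness).
    """

    def __init__(self, capacity: int = 128, overflow: str = "block"):
        if capacity <= 0:
            raise ModelError("capacity must be positive")
        if overflow not in ("block", "drop_oldest"):
            raise ModelError(f"unknown overflow policy {overflow!r}")
        self.capacity = capacity
        self.overflow = overflow
        self.dropped = 0
        self._q: queue.Queue = queue.Queue(maxsize=capacity)
        self._lock = threading.Lock()

    def put(self, item) -> None:
        if self.overflow == "block":
            self._q.put(item)
            return
        while True:
            try:
                self._q.put_nowait(item)
                return
            except queue.Full:
                with self._lock:
                    try:
                        self._q.get_nowait()
                        self.dropped += 1
                    except queue.Empty:
                        pass

    def close(self) -> None:
        # the end-of-stream marker obeys the same overflow policy (a full
        # drop_oldest buffer sheds its oldest payload to make room)
        self.put(_SENTINEL)

    def __iter__(self):
        while True:
            item = self._q.get()
            if item is _SENTINEL:
                return
            yield item


# ---------------------------------------------------------------------------
# latency log
# ---------------------------------------------------------------------------

@dataclass
class LatencyLog:
    """Wall-clock per-frame durations per module, with summary percentiles."""

    durations: dict[str, list[float]] = field(default_factory=dict)

    def record(self, module: str, seconds: float) -> None:
        if seconds < 0:
            raise ModelError("durations must be non-negative")
        self.durations.setdefault(module, []).append(seconds)

    def timed(self, module: str):
        log = self

        class _Timer:
            def __enter__(self):
                self.t0 = _time.perf_counter()

            def __exit__(self, *exc):
                log.record(module, _time.perf_counter() - self.t0)

        return _Timer()

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for module, vals in self.durations.items():
            arr = np.asarray(vals)
            out[module] = {
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "p50": float(np.percentile(arr, 50)),
                "p90": float(np.percentile(arr, 90)),
                "max": float(arr.max()),
            }
        return out
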