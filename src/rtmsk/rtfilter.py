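"""Real-time filtering and differentiation of generalized coordinates.

Incoming samples (constant rate ``fs``) enter a circular buffer of size ``M``
(the filter's memory). The buffered window is smoothed by a low-pass
windowed-sinc FIR (Hamming window, cutoff ``fc``); a generalized
cross-validation (GCV) smoothing spline of order ``Ns`` is then fitted to the
smoothed window and evaluated - value, first and second derivative - at the
delayed time ``t_d = t - D/fs``. The lag ``D`` trades delay for accuracy:
samples a little behind the buffer head have near-symmetric neighbourhoods
and are therefore filtered with almost no phase distortion.

Inside the window the FIR is applied without fabricating data beyond the
buffer: at each window position the symmetric kernel is truncated to the
available samples and renormalized to unit sum, so the smoother stays exactly
linear and preserves constants while degrading gracefully toward the edges.

Also provides the offline zero-lag reference (forward-backward filtering over
a whole trial) and the hyper-parameter selection procedure that picks (M, D)
by minimizing the acceleration RMSE against a reference on a grid.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import BSpline, make_smoothing_spline
from scipy.signal import filtfilt, firwin

__all__ = ["FilterConfig", "FilterOutput", "WARMING_UP", "design_fir",
           "RealTimeFilter", "offline_reference", "tune_hyperparameters"]


@dataclass(frozen=True)
class FilterConfig:
    """Hyper-parameters of the real-time filter.

    M: memory (buffer/kernel size, samples); fc: low-pass cutoff (Hz);
    Ns: spline order; D: evaluation lag (samples); fs: sampling rate (Hz).
    Defaults are the gait regime: fc = 6 Hz at fs = 100 Hz with M = 35,
    D = 14 and a cubic spline.
    """

    M: int = 35
    fc: float = 6.0
    Ns: int = 3
    D: int = 14
    fs: float = 100.0

    def __post_init__(self):
        if not 0 < self.fc < self.fs / 2:
            raise ValueError(f"fc must lie in (0, fs/2), got {self.fc}")
        if not 0 <= self.D < self.M:
            raise ValueError(f"D must lie in [0, M), got {self.D}")
        if self.M < self.Ns + 2:
            raise ValueError(f"M must be >= Ns + 2, got M={self.M}, Ns={self.Ns}")
        if self.Ns < 1:
            raise ValueError("Ns must be >= 1")


@dataclass
class FilterOutput:
    """Filtered value and derivatives evaluated at the delayed time t_d."""

    t_d: float
    value: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray


class _WarmingUp:
    """Sentinel returned until the buffer holds M samples."""

    def __repr__(self):
        return "WARMING_UP"

    def __bool__(self):
        return False


WARMING_UP = _WarmingUp()


def design_fir(M: int, fc: float, fs: float) -> np.ndarray:
    """Windowed-sinc (Hamming) low-pass kernel of length M, unity DC gain."""
    FilterConfig(M=M, fc=fc, fs=fs, D=0)
    kernel = firwin(M, fc, window="hamming", fs=fs)
    return kernel / kernel.sum()


def _smoother_matrix(kernel: np.ndarray) -> np.ndarray:
    """Window smoothing matrix built from the symmetric kernel.

    Row i holds the kernel centred at window position i, truncated to the
    samples actually inside the buffer. Truncated rows are moment-corrected:
    the minimal L2 adjustment is added so each row reproduces the full
    kernel's moments up to cubic order (sum 1, zero phase shift, matched
    second moment, zero third moment). This keeps the effective smoothing
    uniform across the window - crucial because the spline differentiates the
    smoothed window, and uncorrected edge truncation injects spurious
    curvature that dominates the acceleration estimate.
    """
    M = len(kernel)
    c = (M - 1) // 2
    delta_full = np.arange(M) - c
    m_full = np.array([1.0, 0.0, kernel @ (delta_full ** 2.0), 0.0])
    W = np.zeros((M, M))
    for i in range(M):
        lo, hi = max(0, i - c), min(M, i + c + 1)
        kt = kernel[(lo - i + c):(hi - i + c)]
        d = np.arange(lo, hi) - i
        V = np.vander(d, 4, increasing=True).T   # rows: delta^0 .. delta^3
        w = kt + V.T @ np.linalg.solve(V @ V.T, m_full - V @ kt)
        W[i, lo:hi] = w
    return W


def _penalty_matrix(knots: np.ndarray, k: int) -> np.ndarray:
    """Integrated squared-second-derivative penalty for a B-spline basis,
    assembled exactly by Gauss-Legendre quadrature per knot interval."""
    ncoef = len(knots) - k - 1
    basis2 = BSpline(knots, np.eye(ncoef), k).derivative(2)
    xg, wg = np.polynomial.legendre.leggauss(max(k, 3))
    omega = np.zeros((ncoef, ncoef))
    breaks = np.unique(knots)
    for a, b in zip(breaks[:-1], breaks[1:]):
        pts = 0.5 * (b - a) * xg + 0.5 * (a + b)
        rows = basis2(pts)                       # (nq, ncoef)
        omega += 0.5 * (b - a) * (rows.T * wg) @ rows
    return omega


class _WindowSpline:
    """GCV smoothing spline solver precomputed for the fixed window geometry.

    The buffer abscissa is translation invariant (always M uniform samples
    ending at the newest time), so the basis, the penalty, the per-lambda
    solve operators and the evaluation rows at the lag point are all built
    once. Each push then reduces to a handful of small mat-muls, and the
    smoothing parameter is selected by GCV jointly over all channels of the
    window - one lambda per window, which keeps the per-window operator
    linear across channels.
    """

    def __init__(self, M: int, Ns: int, fs: float, D: int,
                 lambdas: np.ndarray | None = None):
        s = (np.arange(M) - (M - 1)) / fs        # relative times, head at 0
        knots = np.concatenate([np.full(Ns + 1, s[0]), s[1:-1], np.full(Ns + 1, s[-1])])
        B = BSpline.design_matrix(s, knots, Ns).toarray()
        omega = _penalty_matrix(knots, Ns)
        BtB = B.T @ B
        self.B = B
        self.M = M
        self.lambdas = np.logspace(-9, 5, 29) if lambdas is None else lambdas
        self._solvers = []                        # (ncoef, M) per lambda
        self._edf = []
        for lam in self.lambdas:
            A = BtB + lam * omega
            S = np.linalg.solve(A, B.T)
            self._solvers.append(S)
            self._edf.append(float(np.trace(B @ S)))
        basis = BSpline(knots, np.eye(B.shape[1]), Ns)
        td = -D / fs
        self._rows = [np.atleast_2d(basis.derivative(nu)(td) if nu else basis(td))[0]
                      for nu in range(3)]

    def fit_eval(self, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fit all channels (columns of Y) with a shared GCV-chosen lambda and
        return (value, velocity, acceleration) at the lag point."""
        best, coef = np.inf, None
        n = self.M
        for S, edf in zip(self._solvers, self._edf):
            c = S @ Y
            rss = float(np.sum((Y - self.B @ c) ** 2))
            gcv = n * rss / max(n - edf, 1e-9) ** 2
            if gcv < best:
                best, coef = gcv, c
        return tuple(row @ coef for row in self._rows)


def _gcv_spline(x: np.ndarray, y: np.ndarray, order: int) -> BSpline:
    """GCV smoothing spline of the given order.

    Order 3 uses scipy's cubic GCV smoothing spline directly. Other orders use
    a penalized B-spline (second-difference penalty) with the smoothing
    parameter selected by minimizing the GCV score on a log grid.
    """
    if order == 3:
        return make_smoothing_spline(x, y)
    t = np.concatenate([np.full(order + 1, x[0]), x[1:-1], np.full(order + 1, x[-1])])
    B = BSpline.design_matrix(x, t, order).toarray()
    n, k = B.shape
    D = np.diff(np.eye(k), 2, axis=0)
    BtB, Bty, DtD = B.T @ B, B.T @ y, D.T @ D
    best = (np.inf, None)
    for lam in np.logspace(-12, 4, 33):
        A = BtB + lam * DtD
        try:
            coef = np.linalg.solve(A, Bty)
            H = B @ np.linalg.solve(A, B.T)
        except np.linalg.LinAlgError:
            continue
        resid = y - B @ coef
        edf = np.trace(H)
        gcv = n * (resid @ resid) / max(n - edf, 1e-9) ** 2
        if gcv < best[0]:
            best = (gcv, coef)
    if best[1] is None:
        raise RuntimeError("GCV spline fit failed")
    return BSpline(t, best[1], order)


class RealTimeFilter:
    """Stateful per-channel real-time filter (circular buffer of size M)."""

    def __init__(self, config: FilterConfig, n_channels: int):
        self.config = config
        self.n_channels = n_channels
        self._buf: deque[np.ndarray] = deque(maxlen=config.M)
        self._t_newest: float | None = None
        self.kernel = design_fir(config.M, config.fc, config.fs)
        self._W = _smoother_matrix(self.kernel)
        self._spline = _WindowSpline(config.M, config.Ns, config.fs, config.D)

    def reset(self) -> None:
        self._buf.clear()
        self._t_newest = None

    def push_and_evaluate(self, t: float, x: np.ndarray) -> FilterOutput | _WarmingUp:
        """Append one sample; once M samples are buffered, return the smoothed
        value and first/second derivatives at t_d = t - D/fs."""
        x = np.atleast_1d(np.asarray(x, float))
        if x.shape != (self.n_channels,):
            raise ValueError(f"expected {self.n_channels} channels, got {x.shape}")
        self._buf.append(x)
        self._t_newest = float(t)
        if len(self._buf) < self.config.M:
            return WARMING_UP
        cfg = self.config
        window = np.asarray(self._buf)          # (M, C)
        smooth = self._W @ window
        t_d = t - cfg.D / cfg.fs
        val, vel, acc = self._spline.fit_eval(smooth)
        return FilterOutput(t_d, val, vel, acc)

    def filter_stream(self, times: np.ndarray, values: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Run the filter over a whole uniform series; returns (t_d, value,
        velocity, acceleration) arrays for the frames past warm-up."""
        self.reset()
        values = np.asarray(values, float)
        if values.ndim == 1:
            values = values[:, None]
        td, vals, vels, accs = [], [], [], []
        for t, row in zip(np.asarray(times, float), values):
            out = self.push_and_evaluate(t, row)
            if out is WARMING_UP:
                continue
            td.append(out.t_d)
            vals.append(out.value)
            vels.append(out.velocity)
            accs.append(out.acceleration)
        return (np.array(td), np.array(vals), np.array(vels), np.array(accs))


def offline_reference(times: np.ndarray, values: np.ndarray, fc: float,
                      Ns: int = 3, kernel_size: int = 35
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Offline (whole-trial) comparator: zero-lag forward-backward low-pass at
    ``fc`` followed by a GCV smoothing spline; returns value, first and second
    derivative at the input timestamps."""
    times = np.asarray(times, float)
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == times.size and values.ndim == 2:
        pass
    else:
        values = values.T
    fs = 1.0 / np.median(np.diff(times))
    kernel = design_fir(kernel_size, fc, fs)
    if times.size <= 3 * kernel_size:
        raise ValueError("trial shorter than the offline filter warm-up")
    filtered = filtfilt(kernel, [1.0], values, axis=0)
    val = np.empty_like(filtered)
    vel = np.empty_like(filtered)
    acc = np.empty_like(filtered)
    for c in range(filtered.shape[1]):
        spl = _gcv_spline(times, filtered[:, c], Ns)
        val[:, c] = spl(times)
        vel[:, c] = spl.derivative(1)(times)
        acc[:, c] = spl.derivative(2)(times)
    return val, vel, acc


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float).reshape(a.shape)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def tune_hyperparameters(times: np.ndarray, values: np.ndarray,
                         reference: Callable[[np.ndarray], tuple],
                         Ms: Sequence[int], Ds: Sequence[int],
                         fc: float = 6.0, Ns: int = 3, fs: float = 100.0):
    """Grid search over (M, D) minimizing the acceleration RMSE.

    ``reference(t_d)`` must return (value, velocity, acceleration) arrays of
    the comparator - analytic truth or an offline-reference interpolant - at
    the requested (delayed) evaluation times. Returns ``(M*, D*)`` plus the
    coordinate/speed/acceleration RMSE surfaces keyed by (M, D). Ties are
    broken toward smaller M, then smaller D.
    """
    Ms, Ds = list(Ms), list(Ds)
    if not Ms or not Ds:
        raise ValueError("empty hyper-parameter grid")
    times = np.asarray(times, float)
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] != times.size:
        values = values.T
    surfaces: dict[tuple[int, int], tuple[float, float, float]] = {}
    best = None
    for M in sorted(Ms):
        for D in sorted(Ds):
            if D >= M:
                continue
            filt = RealTimeFilter(FilterConfig(M=M, fc=fc, Ns=Ns, D=D, fs=fs),
                                  values.shape[1])
            td, val, vel, acc = filt.filter_stream(times, values)
            rv, rs, ra = reference(td)
            err = (_rmse(val, rv), _rmse(vel, rs), _rmse(acc, ra))
            surfaces[(M, D)] = err
            key = (err[2], M, D)
            if best is None or key < best[0]:
                best = (key, (M, D))
    if best is None:
        raise ValueError("no feasible (M, D) pair on the grid")
    return best[1], surfaces
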