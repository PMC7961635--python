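"""Muscle redundancy resolution by per-frame static optimization.

The moment balance tau = R(q) f_m (actuated coordinates only - the floating
base's residual rows are excluded) is under-determined because there are more
muscles than net joint moments. Forces are resolved by minimizing the
normalized-force cost (1/p) sum_i (f_i / f_i^max)^p subject to the balance
and nonnegativity (muscles can only pull); optimizing forces rather than
activations leaves the variables unbounded above, so no reserve actuators
are needed.

The moment arm matrix r_ij = -d(path length_i)/d(q_j) is sampled from the
straight-line/via-point muscle geometry on a coordinate grid, the degrees of
freedom spanned by each muscle are identified from the samples, and a
multivariate polynomial surrogate over the spanned coordinates is fitted for
fast evaluation inside the real-time loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear, minimize

from .model import Model, ModelError, tree_kinematics


# ---------------------------------------------------------------------------
# moment arms from path geometry
# ---------------------------------------------------------------------------

def all_path_lengths(model: Model, q: np.ndarray,
                     muscles: list[str] | None = None) -> np.ndarray:
    """Straight-line path lengths of the listed muscles from a single forward
    kinematics pass."""
    names = muscles or list(model.muscles)
    kin, _ = tree_kinematics(model, q)
    out = np.empty(len(names))
    for i, name in enumerate(names):
        mus = model.muscles[name]
        pts = [kin[seg].origin + kin[seg].rotation.apply(loc) for seg, loc in mus.path]
        length = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            d = float(np.linalg.norm(b - a))
            if d < 1e-12:
                raise ModelError(f"muscle {name}: degenerate zero-length path segment")
            length += d
        out[i] = length
    return out


def muscle_path_length(model: Model, muscle: str, q: np.ndarray) -> float:
    """Total straight-line length of the muscle's path at configuration q."""
    return float(all_path_lengths(model, q, [muscle])[0])


def moment_arm_matrix(model: Model, q: np.ndarray, h: float = 1e-6,
                      muscles: list[str] | None = None,
                      coordinates: list[int] | None = None) -> np.ndarray:
    """Moment arms r_ij = -dl_i/dq_j by central differences (tension
    convention: a positive moment arm maps a pulling muscle to a positive
    generalized force). Columns outside ``coordinates`` (when given) are
    left zero."""
    names = muscles or list(model.muscles)
    n = model.n_coordinates
    cols = range(n) if coordinates is None else coordinates
    R = np.zeros((len(names), n))
    for j in cols:
        qp, qm = np.asarray(q, float).copy(), np.asarray(q, float).copy()
        qp[j] += h
        qm[j] -= h
        R[:, j] = -(all_path_lengths(model, qp, names)
                    - all_path_lengths(model, qm, names)) / (2 * h)
    return R


def sample_moment_arms(model: Model, grid: dict[str, np.ndarray],
                       muscles: list[str] | None = None,
                       fd_coordinates: list[int] | None = None):
    """Evaluate the moment arm matrix on the tensor grid of the given
    coordinates (others held at zero).

    Returns ``(points, samples)``: the (npts, nq) array of grid
    configurations (full coordinate vectors) and the (npts, nmuscles, nq)
    moment-arm samples.
    """
    names = muscles or list(model.muscles)
    coords = list(grid)
    for c in coords:
        if c not in model.coordinate_names:
            raise ModelError(f"unknown coordinate {c!r}")
    axes = [np.asarray(grid[c], float) for c in coords]
    idx = [model.coordinate_index(c) for c in coords]
    points, samples = [], []
    for combo in itertools.product(*axes):
        q = np.zeros(model.n_coordinates)
        for j, v in zip(idx, combo):
            q[j] = v
        points.append(q)
        samples.append(moment_arm_matrix(model, q, muscles=names,
                                         coordinates=fd_coordinates))
    return np.array(points), np.array(samples)


def identify_spanned_dofs(samples: np.ndarray, eps: float = 1e-6
                          ) -> list[list[int]]:
    """Coordinate j is spanned by muscle i iff max |r_ij| over the grid
    exceeds eps (metres)."""
    peak = np.max(np.abs(samples), axis=0)       # (nmuscles, nq)
    return [list(np.nonzero(row > eps)[0]) for row in peak]


# ---------------------------------------------------------------------------
# polynomial surrogate
# ---------------------------------------------------------------------------

def _monomial_exponents(nvars: int, degree: int) -> list[tuple[int, ...]]:
    return [e for e in itertools.product(range(degree + 1), repeat=nvars)
            if sum(e) <= degree]


@dataclass
class MomentArmModel:
    """Per (muscle, coordinate) multivariate polynomial moment arms over each
    muscle's spanned coordinates."""

    muscle_names: list[str]
    spanned: list[list[int]]                       # coordinate indices per muscle
    degree: int
    coefficients: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    exponents: dict[int, list[tuple[int, ...]]] = field(default_factory=dict)
    max_residual: float = 0.0

    def evaluate(self, q: np.ndarray, actuated_slice: slice | None = None) -> np.ndarray:
        """Moment arm matrix (ncoords, nmuscles) at q; structurally zero
        outside each muscle's spanned set. With ``actuated_slice`` the rows
        are restricted (e.g. to the actuated coordinates)."""
        n = len(q)
        R = np.zeros((n, len(self.muscle_names)))
        for i, span in enumerate(self.spanned):
            if not span:
                continue
            x = q[span]
            basis = np.array([np.prod(x ** np.array(e)) for e in self.exponents[i]])
            for j in span:
                R[j, i] = basis @ self.coefficients[(i, j)]
        return R[actuated_slice] if actuated_slice is not None else R


def fit_moment_arm_polynomials(points: np.ndarray, samples: np.ndarray,
                               muscle_names: list[str],
                               spanned: list[list[int]] | None = None,
                               degree: int = 4) -> MomentArmModel:
    """Least-squares multivariate polynomial fit of each (muscle, coordinate)
    moment arm over the muscle's spanned coordinates (total degree bound)."""
    if spanned is None:
        spanned = identify_spanned_dofs(samples)
    model = MomentArmModel(list(muscle_names), spanned, degree)
    max_resid = 0.0
    for i, span in enumerate(spanned):
        if not span:
            model.exponents[i] = []
            continue
        expo = _monomial_exponents(len(span), degree)
        X = points[:, span]
        A = np.array([[np.prod(row ** np.array(e)) for e in expo] for row in X])
        if A.shape[0] < A.shape[1]:
            raise ModelError(
                f"muscle {muscle_names[i]}: {A.shape[0]} samples cannot "
                f"determine {A.shape[1]} polynomial coefficients")
        model.exponents[i] = expo
        for j in span:
            y = samples[:, i, j]
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            model.coefficients[(i, j)] = coef
            max_resid = max(max_resid, float(np.max(np.abs(A @ coef - y))))
    model.max_residual = max_resid
    return model


def build_moment_arm_model(model: Model, ranges: dict[str, tuple[float, float]] | None = None,
                           points_per_dof: int = 9, degree: int = 4) -> MomentArmModel:
    """Convenience pipeline: sample on a tensor grid per muscle's coordinates,
    identify spanned DoFs, and fit the polynomial surrogate.

    The grid covers each actuated coordinate's range (default +-1 rad) with
    ``points_per_dof`` points. Muscles span few coordinates, so the grid is
    built per muscle over its own spanned set to keep the tensor small.
    """
    ranges = ranges or {}
    names = list(model.muscles)
    # cheap probe: vary one actuated coordinate at a time (3 values each) and
    # difference only along it to find the spanned coordinates per muscle
    probe = []
    for c in model.coordinate_names[model.n_base:]:
        j = model.coordinate_index(c)
        for v in np.linspace(*ranges.get(c, (-1.0, 1.0)), 3):
            q = np.zeros(model.n_coordinates)
            q[j] = v
            probe.append(moment_arm_matrix(model, q, muscles=names, coordinates=[j]))
    spanned = identify_spanned_dofs(np.array(probe))

    full = MomentArmModel(names, spanned, degree)
    max_resid = 0.0
    for i, name in enumerate(names):
        span = spanned[i]
        if not span:
            full.exponents[i] = []
            continue
        grid = {model.coordinate_names[j]: np.linspace(
            *ranges.get(model.coordinate_names[j], (-1.0, 1.0)), points_per_dof)
            for j in span}
        pts, smp = sample_moment_arms(model, grid, muscles=[name],
                                      fd_coordinates=span)
        sub = fit_moment_arm_polynomials(pts, smp, [name], [span], degree)
        full.exponents[i] = sub.exponents[0]
        for j in span:
            full.coefficients[(i, j)] = sub.coefficients[(0, j)]
        max_resid = max(max_resid, sub.max_residual)
    full.max_residual = max_resid
    return full


# ---------------------------------------------------------------------------
# redundancy solver
# ---------------------------------------------------------------------------

@dataclass
class MuscleForces:
    forces: np.ndarray
    objective: float
    residual_norm: float
    iterations: int
    feasible: bool


def solve_muscle_redundancy(R: np.ndarray, tau: np.ndarray, fmax: np.ndarray,
                            p: int = 2, warm_start: np.ndarray | None = None,
                            tol: float = 1e-9, max_iterations: int = 200
                            ) -> MuscleForces:
    """Minimize (1/p) sum (f_i/fmax_i)^p s.t. R f = tau, f >= 0.

    ``R`` is the actuated-rows moment arm matrix (ncoords_actuated, nmuscles).
    Solved with SLSQP (analytic gradient and constraint Jacobian), warm-started
    when a previous solution is supplied. An infeasible balance (tau outside
    the cone of R with f >= 0) is flagged and answered with the nonnegative
    least-squares fallback, reporting the nonzero residual.
    """
    R = np.atleast_2d(np.asarray(R, float))
    tau = np.atleast_1d(np.asarray(tau, float))
    fmax = np.atleast_1d(np.asarray(fmax, float))
    if p not in (2, 3):
        raise ModelError("power exponent p must be 2 or 3")
    if np.any(fmax <= 0):
        raise ModelError("fmax must be positive")
    if not np.all(np.isfinite(R)):
        raise ModelError("moment arm matrix must be finite")
    m = R.shape[1]
    x0 = np.zeros(m) if warm_start is None else np.clip(warm_start, 0.0, None)

    def objective(f):
        z = f / fmax
        return float(np.sum(np.abs(z) ** p) / p)

    def gradient(f):
        z = f / fmax
        return np.sign(z) * np.abs(z) ** (p - 1) / fmax

    res = minimize(objective, x0, jac=gradient, method="SLSQP",
                   bounds=[(0.0, None)] * m,
                   constraints=[{"type": "eq", "fun": lambda f: R @ f - tau,
                                 "jac": lambda f: R}],
                   options={"maxiter": max_iterations, "ftol": 1e-14})
    f = np.clip(res.x, 0.0, None)
    resid = float(np.linalg.norm(R @ f - tau))
    tol_ok = resid <= 1e-6 * (1.0 + np.linalg.norm(tau))
    if res.success and tol_ok:
        return MuscleForces(f, objective(f), resid, res.nit, True)
    # fallback: nonnegative least squares on the balance
    fb = lsq_linear(R, tau, bounds=(0.0, np.inf), tol=1e-12)
    f = np.clip(fb.x, 0.0, None)
    resid = float(np.linalg.norm(R @ f - tau))
    return MuscleForces(f, objective(f), resid, res.nit,
                        resid <= 1e-6 * (1.0 + np.linalg.norm(tau)))


def solve_frame(model: Model, arm_model: MomentArmModel, q: np.ndarray,
                tau_actuated: np.ndarray, p: int = 2,
                warm_start: np.ndarray | None = None) -> MuscleForces:
    """Evaluate the polynomial moment arms at q and resolve the redundancy
    for one frame (actuated coordinates only; base residual rows excluded)."""
    R = arm_model.evaluate(np.asarray(q, float),
                           actuated_slice=slice(model.n_base, None))
    fmax = np.array([model.muscles[n].fmax for n in arm_model.muscle_names])
    return solve_muscle_redundancy(R, tau_actuated, fmax, p=p, warm_start=warm_start)
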