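# Methods

This note documents the models, numerical choices and design decisions behind
`rtmsk`, and what the synthetic test bed does and does not establish.

## Rigid-body model and kinematics

The model is a tree of rigid segments rooted at the ground (y-up, x forward,
z lateral; SI units, radians). Joints are revolute, free-planar (2
translations + 1 rotation) or free-spatial (3 translations + 3 intrinsic
rotations); each joint is decomposed into elementary prismatic/revolute
degrees of freedom so that position, velocity and acceleration propagate
through one uniform, exact recursion — no finite differencing anywhere in the
kinematics. Rotations are held as quaternions (scipy `Rotation`), renormalized
by construction on every composition. Coordinate order is depth-first from
the ground with the base joint first, and is deterministic across loads.

Model files are a small declarative YAML schema (`segments`, `joints`,
`markers`, `imus`, `muscles`) carrying exactly the fields the pipeline needs.
Loading validates masses, inertia symmetry/positive-semidefiniteness and the
principal-moment triangle inequality, tree structure, and referential
integrity; closed kinematic loops are out of scope (loop constraints can only
enter the IK objective as a penalty).

## Inverse kinematics

Each frame solves a weighted nonlinear least-squares problem over marker
position residuals and IMU orientation residuals (the geodesic rotation
vector of `R_virtualᵀ R_experimental`). The solver is a damped Gauss–Newton
(Levenberg regularization, adaptive damping) on the stacked residuals with
analytic Jacobians: geometric point Jacobians for markers and the angular
Jacobian mapped through the exact differential of the rotation logarithm for
orientations. Solves are warm-started from the previous frame; a descent
guarantee returns the initial point (flagged) if no improvement is found.
Holonomic-constraint penalties are supported as user callables with a weight;
for tree models the term is identically zero. The stopping rule is a gradient
/ step / cost-decrease threshold at 1e-12 with a 100-iteration cap — chosen
so noise-free round trips reach the 1e-6 rad regime with a handful of
iterations.

IMU calibration assumes a static pose matching the model default pose:
per-sensor orientations are quaternion-averaged over the static window, and
the heading rotation about the vertical aligns the *horizontal projection* of
the base sensor's anterior axis with the model's anterior axis — projecting
first makes the yaw estimate immune to pitch/roll placement error of the base
sensor. The composed offset is constant for the session and pre-multiplies
every sensor stream.

Marker completion: a segment with ≥ 3 visible markers rebuilds its missing
ones by the Kabsch/orthogonal-Procrustes rigid fit from model-frame to world
positions; with < 3 visible the last known positions are held and the frame
is flagged. The completion never hard-fails and reports what it did.

Multi-source streams are resampled onto a shared uniform grid anchored at the
latest stream start: linear interpolation per marker axis, spherical linear
interpolation for orientations.

## Real-time filtering and differentiation

State: a circular buffer of the last `M` samples per channel. Per push:

1. **FIR smoothing.** A windowed-sinc low-pass (Hamming window, cutoff `f_c`,
   `M` taps, unit DC gain) is applied across the buffered window. At window
   positions where the symmetric kernel would extend beyond the buffer, the
   kernel is truncated to the available samples and *moment-corrected*: the
   minimal-L2 adjustment is added so every row keeps the full kernel's
   moments up to cubic order (sum one, zero phase shift, matched second
   moment, zero third moment). No data outside the buffer is fabricated, the
   operator stays linear, constants and cubics pass undistorted, and — the
   point of the correction — the edge rows do not inject spurious curvature
   into the window, which would otherwise dominate the spline's second
   derivative. (Plain renormalized truncation was measured to produce ~30%
   acceleration error on a clean gait-band sinusoid; the corrected rows bring
   it to ~1%.)
2. **GCV smoothing spline.** A penalized regression spline of order `N_s`
   (default cubic) with the exact integrated-squared-second-derivative
   penalty is fitted to the smoothed window. The smoothing parameter is
   selected every frame by generalized cross-validation over a fixed log-grid
   — jointly across all channels of the window, so each frame applies one
   linear smoothing operator to all coordinates (this is also what makes the
   per-window filter exactly linear across channels). Because the window
   abscissa is translation-invariant, the basis, penalty, per-λ solve
   operators and evaluation rows are all precomputed once; a push costs a few
   small matrix products (~0.3 ms for 9 channels).
3. **Delayed evaluation.** Value, velocity and acceleration are reported at
   `t_d = t − D/f_s`. Points a little behind the head have near-symmetric
   neighbourhoods, so a modest `D` sharply improves derivative quality.

Defaults for gait: `f_c = 6 Hz`, `N_s = 3` (higher orders over-fit short
windows), `M = 35`, `D = 14` at `f_s = 100 Hz`. The offline comparator
(`offline_reference`) applies the same kernel forward–backward (zero lag)
over the whole trial and fits one GCV spline; `tune_hyperparameters` selects
`(M, D)` on a grid by acceleration RMSE against a comparator, breaking ties
toward smaller `M` then smaller `D` (shorter memory and lag are preferable at
equal error).

## Inverse dynamics and residuals

Given full kinematics and external wrenches (point + force + moment in the
ground frame), generalized forces are computed by projecting each segment's
net inertial-minus-applied wrench onto the elementary joint axes — the
Jacobian-transpose form of the recursive Newton–Euler balance, algebraically
identical to the backward recursion for trees and exact to machine precision
(verified against a symbolic Lagrangian on the double pendulum at 1e-15
relative). Gravity is `(0, −9.80665, 0) m/s²`. The base joint block is the
floating-base residual — the non-physical wrench absorbing model/data
inconsistency — reported separately (`residual_report`) as the pipeline's
quality diagnostic and never redistributed. A mass-matrix/forward-dynamics
helper exists for round-trip tests only; forward simulation is not a feature.

## GRF&M prediction

The total external wrench is the Newton–Euler sum over segments, resolved
about the ground origin with COM cross terms (per-endpoint force terms are
absorbed into the resolved moment since only the per-foot totals are
unknown). The per-leg split works in a walking-direction frame obtained from
the circular-mean yaw of the pelvis anterior axis's horizontal projection.

Gait phases come from a per-leg debounced threshold detector: raw state is
stance iff the measure `u(t)` is at or above threshold; the committed state
flips after `k` consecutive opposite detections, with the event timestamped
at the first sample of the committing run. The measure is injectable: the
default is the (negated) height of the heel endpoint above the ground plane
with a 0.02 m threshold and `k = 3`; an insole-style binary contact channel
can be supplied instead. Double/single-support durations are estimated online
from consecutive events, with configurable initial defaults used until the
first estimates exist.

During single support the stance leg receives the whole wrench. During double
support the trailing leg receives the totals *cached at the leading leg's
heel strike*, scaled element-wise by a monotone transition function of the
normalized double-support time (default smoothstep `1 − (3s² − 2s³)`;
linear and table-driven per-component shapes are configurable); the leading
leg takes the remainder, so conservation holds identically at every sample.
The cached value is held fixed across the double support. Before the first
observed heel strike the distributor falls back to single support on the most
recent stance leg (ties to the right leg, deterministically).

The CoP of the single-support leg advances from the heel to the
metatarsophalangeal projection as `heel + σ·d` with
`σ(t) = −(2/3π)[sin ωt − sin 2ωt/8 − ¾ ωt]`, `ω = 2π/T_ss` (monotone, flat at
both ends, σ(T_ss/2) = ½). During double support the trailing CoP is pinned
at the metatarsophalangeal projection and the leading CoP at the heel
projection — the σ model governs single support only. Per-leg moments are
re-expressed about the assigned CoP, which leaves the equivalent wrench
unchanged.

## Muscle redundancy

Moment arms are defined by the tension convention `r_ij = −∂ℓ_i/∂q_j`
(path length ℓ from the straight-line/via-point geometry, central differences
with `h = 1e-6` rad on a single shared forward-kinematics pass per
perturbation). Spanned coordinates are identified per muscle as those where
`max |r| > 1e-6 m` over a probe grid; a multivariate polynomial (total degree
4 by default, 9 grid points per spanned coordinate over ±1 rad) is fitted per
(muscle, coordinate) for fast evaluation, with the maximum fit residual
reported (≈1e-4 m for the walker's muscles, whose true moment arms are not
polynomial).

The per-frame program minimizes `(1/p) Σ (fᵢ/fᵢᵐᵃˣ)ᵖ` subject to the moment
balance on the actuated coordinates only (the floating base's rows are
excluded — for a 6-DoF base that removes exactly six equality constraints)
and `f ⪰ 0`; there is deliberately no upper bound on forces, which avoids
reserve actuators. `p = 2` (default, unique optimum for full-row-rank `R`)
and `p = 3` are solved with SLSQP using analytic gradients and constraint
Jacobians, tolerance 1e-14 on the objective, 200 iterations, warm-started
from the previous frame. An infeasible balance is flagged and answered by a
nonnegative least-squares fallback with its residual reported. Scaling all
`fᵢᵐᵃˣ` by c leaves the optimizer's argmin unchanged and scales the objective
by `c^-p` (the objective is a monotone transform of itself under that
scaling).

## Joint reactions

The reaction wrench on the child at each joint centre (ground frame — the
frame/point is recorded on the result) balances the distal subtree: subtree
inertial wrench minus gravity, muscle path forces and external wrenches
applied within the subtree. Muscle tensions act along the unit directions of
their path at every attachment/via point, equal and opposite across adjoining
segments, so equal co-contraction changes the joint's compressive load
without changing the net moment. Residual inconsistency surfaces in the base
joint's reaction, matching the inverse-dynamics residual block exactly.
Medial/lateral compartment splitting is out of scope (it needs articular
geometry the rigid models do not carry).

## Synthetic test bed

`synthetic.make_fixture` provides a pendulum, a double pendulum (the
symbolic-oracle model) and a planar walker: 7 segments, 9 DoF (3-DoF planar
base + bilateral hip/knee/ankle pins about z), anthropometric mass fractions
(thigh 0.100, shank 0.0465, foot 0.0145 of a 75 kg subject, remainder lumped
into the pelvis/trunk segment, scaled exactly to any requested subject mass),
≥3 non-collinear markers and one IMU frame per segment, heel and
metatarsophalangeal endpoints per foot, and 12 straight-line muscles forming
an antagonist pair at every joint (so any actuated moment is feasible with
nonnegative tensions).

Gait kinematics are band-limited Fourier series per coordinate (two
harmonics, amplitudes of a few tenths of a radian around standing posture)
with a 1.1 s cycle, constant 1.2 m/s base progression, a small vertical
bounce and yaw sway — chosen as typical adult walking scales. Events follow a
fixed schedule (right heel-strike at multiples of T; each double support is
10% of the cycle, so stance is 60%), aligned to the sampling grid; trials
start 0.3 T into the cycle (inside right single support) so the causal
predictor and the schedule agree from the first sample. Observation noise:
iid Gaussian marker jitter, Bernoulli occlusions, small-angle IMU noise plus
a linear-in-time yaw drift. Everything is seeded and bit-reproducible.

Ground-truth per-leg wrenches apply the same smooth-transition rules driven
by the exact schedule. Two things follow. First, inverse dynamics with these
wrenches gives base residuals at machine precision *by construction* (the
split conserves the computed total), for any trajectory — this tests the
bookkeeping, not biological fidelity. Second, the predictor fed with
noise-free kinematics and the schedule's contact indicator (debounce k = 1,
period defaults set to the schedule's values) must reproduce the ground truth
to machine precision — any discrepancy is an implementation defect, which is
exactly what the round-trip acceptance tests assert. What the synthetic bed
does **not** show: that the smooth transition assumption, the CoP model or
the heel-height detector are accurate for real human gait (the walker's
waveforms are not physiological, the ground truth is defined through the same
transition model, and real marker noise is neither iid nor Gaussian).

The full-pipeline round trip evaluates the dynamic chain on the generator's
analytic derivatives; the filter's own error budget is assessed separately
(real-time acceleration RMSE within 3× of the whole-trial zero-lag reference
on noisy gait kinematics, σ = 0.005 rad at 100 Hz) because any causal filter
necessarily smooths the true signal and would mask the exactness of the
dynamic round trip.

## Pipeline and I/O

The runner mirrors a two-thread architecture: an acquisition loop (marker
completion + IK per arriving frame) feeds a bounded thread-safe FIFO; the
processing loop consumes frames through filter → GRF&M prediction (or
measured wrenches) → inverse dynamics → muscle optimization → joint
reactions. The buffer's overflow policy is `block` (deterministic,
replay-identical; the default here) or `drop_oldest` (real-time freshness,
drops counted); a single-threaded `--replay` mode executes identically and
is asserted to produce value-identical outputs. Filter lag is carried
explicitly in the output timestamps (`t_d`), never silently shifted;
comparisons against offline references shift explicitly. Per-module
wall-clock latencies are logged with summary percentiles.

File formats: TRC marker trajectories (missing markers as blank fields),
STO/MOT time-series with validated `nRows`/`nColumns` headers, and quaternion
CSV (`time, <name>_w, _x, _y, _z`). Write→read round trips are
value-identical. GRF tables use the
`<leg>_ground_force_v*/p*, <leg>_ground_torque_*` column layout.

## Known limitations

- Straight-line/via-point muscle paths only: no wrapping surfaces, no
  activation/contraction dynamics (redundancy is resolved statically).
- The GRF&M predictor assumes walking (alternating support with no flight
  phase); running and stairs are out of scope, as is any learned predictor.
- No subject scaling/calibration from static trials; models are declared,
  not fitted.
- Orientation estimation from raw IMU signals (gyro/accel/mag fusion,
  magnetic disturbance rejection) is upstream of this package; it consumes
  orientation streams.
- The GCV smoothing parameter is re-estimated every window; a frozen-λ mode
  was considered and rejected for simplicity, at the cost of a formally
  nonlinear (though empirically benign) dependence of the filter on signal
  amplitude across windows.
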