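# Methods

This note documents the models, numerical choices and study protocols
implemented in `qmreff`, in the spirit of a methods section: what is
computed, under which assumptions, and what the synthetic studies do and do
not show.

## The efficiency metric

A voxel is a single pool of spins with parameters
p = {T1, T2, M0, φ0, ω0}.  For an unbiased estimator of a parameter θ the
precision is summarized by the parameter-to-noise ratio θNR = θ/σ_θ, and
the *intrinsic efficiency* normalizes it by the experiment's resources:

    η(θ) = (θ / σ_θ) · (σ0 / M0) · T_acq^{-1/2}     [s^{-1/2}]

where SNR_max = M0/σ0 is the best single-measurement SNR the hardware could
deliver (M0 measured by a 90° pulse from thermal equilibrium) and T_acq the
total acquisition duration.  Setting σ_θ to its Cramér–Rao lower bound
turns η into an upper bound that depends only on the spin dynamics of the
sequence; we assume the reconstruction extracts all encoded information, so
equality is used throughout.  η is exactly invariant to σ0 and M0 rescaling
and to back-to-back repetition of the same acquisition — the metric
measures information per unit time, not per experiment.

**Noise and Fisher conventions.** σ0 is the per-quadrature standard
deviation of complex Gaussian measurement noise; for complex data the
Fisher matrix is F = Re(Jᴴ J)/σ0², with J the Jacobian of the stacked
complex signals with respect to all jointly estimated parameters.
Spoiled-only sequence sets estimate {T1, T2, M0}; as soon as a balanced
readout participates, {φ0, ω0} join the set.  Singular Fisher matrices
(unidentifiable parameters) yield σ_θ = ∞ and η = 0 with a structured
warning rather than an exception, so optimizers can traverse degenerate
designs.  Derivatives are central finite differences (relative step 1e-4,
floor 1e-6 in native units) for T1, T2, ω0; the M0 column is s/M0 (the
models are exactly linear in M0) and the φ0 column is i·s.

## Signal models

* **SPGR** — ideally spoiled Ernst steady state,
  s = M0 sin α (1−E1)/(1−E1 cos α)·e^{iφ0}, E1 = e^{−TR/T1}.  Echo-time
  decay of a spoiled readout is a T2\* effect outside the single-pool
  model and is omitted, so SPGR carries no T2 information (as in DESPOT1).
* **bSSFP** — the per-TR affine map (RF rotation, precession, relaxation)
  is solved for its fixed point in the frame rotating with the RF phase
  cycle; the signal is read at TE with e^{−TE/T2} decay and the
  off-resonance phase 2π ω0 TE.  The phase-cycling increment is a free
  per-measurement setting (180° alternating by default).  The complex
  signal acquires a TE-dependent phase ramp across bands; the *magnitude*
  is exactly periodic in ω0 with period 1/TR.
* **DESS / TESS** — the fixed point of the per-TR EPG operator of a
  constant-flip gradient-spoiled sequence; the 2 (resp. 3) echoes are the
  post-RF configuration amplitudes F_0, F_−1 (and F_+1), read at TE.  This
  pathway convention is one of several in use; it fixes phases
  consistently and is validated against a per-isochromat oracle.
* **Spoiled fingerprinting trains** — extended-phase-graph propagation
  with one ideal unit crusher per TR and no RF spoiling.  Per pulse: RF
  rotation, readout of F_0 at TE, relaxation over the TR, crusher shift.
  The truncation order grows adaptively whenever the highest tracked
  order holds more than 1e-12·M0; short-TR constant-flip sequences carry
  configuration tails over ~T2/TR orders, so the order is capped (256
  transient / 128 steady-state) and a warning is raised only if the
  discarded amplitude is non-negligible against M0.
* **Balanced fingerprinting trains** — single-isochromat Bloch recursion
  in the complex representation (M+ = Mx + iMy, Mz), with per-pulse RF
  phases (0/180° alternating by default) and signals demodulated by the
  phase of the exciting pulse.  No initial inversion is prepended by
  default (flip trains may develop one, since flips range over [0°, 180°]).

All pulses are instantaneous rotations; slice profiles, finite pulses,
B1+, magnetization transfer, diffusion and multi-compartment effects are
out of scope.  Angles are degrees at interfaces and radians internally;
times are ms, with T_acq converted to seconds inside η.  T_acq is the sum
of the TRs (a DESS/TESS scan contributes one TR for its 2–3 echoes); an
optional recovery delay after a train is excluded unless explicitly
included, which deliberately "privileges" sequences starting from thermal
equilibrium.

**Driven equilibrium.** A cyclically repeated train is evaluated from the
periodic fixed point m\* of the full-cycle map A, which is affine and
ℝ-linear (the crusher shift conjugates the amplitude crossing order zero).
The public operation solves (I − A)m\* = b directly in real-stacked
coordinates and guarantees ‖A(m\*) − m\*‖ ≤ 1e-10·M0, with a least-squares
fallback for a singular cycle map.  Batched evaluations (design gradients)
use a vectorized extrapolated fixed-point iteration (Aitken acceleration of
the dominant decay mode) when the dense cycle matrix would be too large;
the two paths agree to < 1e-12 and are cross-tested.

## Sequence optimization

Acquisition settings u are chosen to minimize

    Σ_{p∈P} η(T1; p, u)^{-2} + η(T2; p, u)^{-2}

subject to bounds and method structure, with zero-efficiency designs
contributing a finite cap of 1e12 per term so gradient-based solvers can
traverse them.  The solver is SLSQP from random multi-starts (default 100
when the dimension allows; flips drawn uniformly, TRs log-uniformly within
bounds; ties resolve to the lowest start index; individual start failures
are logged and skipped).  Designs above 400 variables use one documented
initialization.  For large bounds-only flip-train problems an L-BFGS-B
option converges substantially faster and is used by the scaled-down
cross-method comparison; SLSQP remains the solver whenever general
constraints are present.  Cost gradients are evaluated in single
vectorized model sweeps (central differences up to 100 design variables,
forward differences beyond).

Per-method design spaces: spoiled fingerprinting optimizes per-pulse flips
and TRs; balanced fingerprinting optimizes flips with TR fixed at 5 ms;
DESPOT/JSR optimizes per-measurement flips and TRs of a mixed set (one
SPGR per five measurements, remainder bSSFP with alternating 180°/0°
phase-cycling increments); PLANET is the constrained case of a single flip
and TR shared by a uniformly phase-cycled bSSFP set (2 free variables);
DESS/TESS optimize one flip and TR per scan of 2 (resp. 3) echoes — a
single DESS scan cannot identify {T1, T2, M0} (two co-phased echoes), so
its measurement grid means multiple scans.  Balanced methods are scored
over an off-resonance grid (−100…100 Hz in 5 Hz steps by default, the
white-matter point T1 = 781 ms / T2 = 65 ms, M0 = 1, φ0 = 0); spoiled-only
methods use ω0 = 0.  Default bounds: flips ∈ [0°, 180°], TR ∈ [TE+1, 20] ms
for catalogue methods; the few-pulse cyclic fingerprint example frees its
inter-pulse delays in [2.3, 3000] ms (2.3 ms = TE + the 0.3 ms minimum
readout margin).  Fingerprinting acquisitions shorter than 400 excitations
are flagged as not spatially encodable.

**Few-pulse fingerprint example.**  Optimizing 5 flips and 5 delays of a
cyclically repeated spoiled train for white matter concentrates the
information into a short 60°–180° spin-echo-like segment, a ~90° readout
and a long recovery period.  Under the [2.3, 3000] ms delay bounds the
best design found (cost 50.1) retains five nonzero pulses — with ideal
instantaneous pulses, extra 180° refocusing pulses at the minimal 2.3 ms
spacing add echo readouts at almost no T2 or time cost — while the best
three-pulse design (61.5°, 180°, 87.1°, cost 52.2, only 4% worse) is the
solution whenever two flips are pinned to zero.  Physical constraints
that instantaneous-pulse models do not see (finite pulse and crusher
durations, SAR) disfavour the minimal-spacing stacking in practice; the
delay bounds are configurable for that reason.

**Scaled-down cross-method comparison.**  The transient-vs-steady-state
ratio study optimizes balanced fingerprinting (N = 400, TR 5 ms, thermal
start) with a single sinusoidal-lobe initialization on a coarse 5-point ω0
grid (L-BFGS-B, 300 iterations), and DESPOT/JSR (n = 10) by 40-start SLSQP
on the full 41-point grid — a 20-variable design optimized on only 5
frequencies overfits them badly, while the 400-pulse train generalizes
smoothly, so the asymmetric treatment is what keeps the comparison fair at
desk scale.  Both final designs are then evaluated on the full grid and
η is averaged over ω0 before taking the T1 and T2 ratios.  At this scale
the measured geometric-mean ratio is ≈ 2.9–3.0 (T1 ratio ≈ 3.3, T2 ratio
≈ 2.6); the single-initialization, coarse-grid transient optimization is
the binding approximation — every increase in its optimization quality
moved the ratio upward, and its cost was still slowly improving at the
iteration cap.

## Undersampling: the dynamics factor

Zero-filled reconstruction treats aliasing as noise.  With aliasing
modelled as independent Gaussian noise, σ_image,R² = σ_alias² + R·σ_image²
and the parameter-error amplification of a least-squares fit is
d_R = σ_image,R / (√R σ_image) = √((1/R)(SNR_image/SaR_image)² + 1), with
η_R = η/d_R.  The Monte-Carlo study estimates σ_image,R per pixel across
trials on the Shepp–Logan phantom (modified 10-ellipse table, values in
[0, 1]) and averages d_R over the nonzero support.

Numerical conventions: orthonormal FFTs; SNR_image = (mean support
intensity)/(per-quadrature image noise of the fully sampled
reconstruction); per-pixel standard deviations are per-quadrature
equivalents √((var_re+var_im)/2), so R = 1 gives d_R = 1 identically.
Random masks sample exactly ⌊N/R⌉ points with the central 4×4 block always
included; reconstruction uses density-compensation weights (1 on the
centre block, the inverse sampling rate elsewhere), which makes the
reconstruction unbiased over mask draws — a single global scale would
over-weight the forced centre by R and destroy the correspondence between
the SaR measurement and the trial variance.  Spirals are variable-density
Archimedean trajectories (radial gap growing linearly from 1 grid unit at
the centre to a calibrated outer gap such that the sampled fraction ≈ 1/R)
rasterized to the nearest Cartesian points, with empirical radial density
compensation; no gridding/NUFFT is performed, so trajectory fidelity is
approximate.  Masks are redrawn (spirals re-rotated) each trial — along a
fingerprinting timecourse aliasing behaves as pseudo-noise — with a
fixed-mask mode for ablation, under which the aliasing becomes a
deterministic bias and d_R collapses to ~1.  The Gaussian-aliasing
assumption is reported as an excess-kurtosis diagnostic, not enforced.
SaR_image comes from one noiseless undersampled reconstruction (rms
residual over the support); the aliasing-to-signal ratio 1/SaR is fitted
as k·√(R−1) through the origin, and d_R ≈ √(k²(R−1)/R·SNR² + 1) closes the
model.  Desk-scale runs use 5,000 trials at 128² (the test suite uses
1,000–2,000 per setting; Monte-Carlo error of the support-averaged d_R is
well below the asserted tolerances).

What the phantom study does not show: multi-coil g-factors, gridding
errors of true non-Cartesian readouts, and model-based or regularized
reconstructions, which resolve aliasing rather than average it and should
lower d_R.

## Synthetic repeat-experiment validation

The DESPOT1 validation harness replaces an in-vivo acquisition with a
two-region digital phantom (T1 = 781 and 1200 ms, M0 = 1, 32×32 by
default) scanned as 10 repeats of 6 SPGR flips {5,8,10,13,15,18}° at
TR = 20 ms with complex Gaussian noise (σ0 known to the harness;
SNR_max = 200).  Each repeat is fitted per pixel by the DESPOT1
linearization on magnitude images (slope e^{−TR/T1}; slopes outside (0,1)
flagged invalid); for every subset of ≥ 3 flips the empirical efficiency
uses the spread of T1 across repeats, pooling per-pixel variances over
each homogeneous region before inverting — inverting each pixel's
10-repeat sample standard deviation first would inflate η_emp by
~3/(4(n−1)) ≈ 8% through the convexity of 1/s.  The theoretical
counterpart is the CRLB efficiency of the same subset with parameters
{T1, M0}.

At these settings the empirical-vs-theoretical regression over all 42
subsets × 2 regions reaches R² ≈ 0.97 with mean ratio ≈ 0.97: the
linearized estimator tracks the bound except for ill-conditioned
high-flip-only subsets, where it cannot attain it.  Magnitude (Rician)
bias is a few percent at SNR_max = 200 — the SPGR signals are only 2–5% of
M0 — and falls below 1% at SNR_max = 1000; the harness therefore
demonstrates the unbiasedness regime rather than assuming it.  Agreement
here shows the metric's bookkeeping (noise propagation, timing, subset
structure) is right; it cannot probe B1 errors, incomplete spoiling,
registration or segmentation effects that a real experiment faces.

## Reproducibility

All randomness flows from a single integer seed through named substreams
(optimizer starts, Monte-Carlo trials, mask draws, noise).  CLI runs embed
their full configuration in every output file, and repeated runs with the
same options are byte-identical.
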