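# Model and methods

`fluidcargo` simulates the transport of a spherical cargo along a
microtubule (MT) by a team of identical kinesin-1 motors whose anchor
points may diffuse on the cargo surface.  This note records the model,
its assumptions, the numerical choices, and what the shipped tests and
the acceptance script do and do not demonstrate.

## Geometry and state

The MT is an infinite rigid cylinder of radius r_MT = 12.5 nm along +x
with its axis at y = z = 0; its protofilament lattice is not resolved.
The cargo is a rigid sphere of radius R (250 nm by default) carrying N
motors.  Each motor has an anchor A⃗ constrained to the cargo surface
and, while bound, a head on the MT.  The head's mechanical position is a
point on the cylinder surface at the azimuth of the anchor's (y, z)
projection, fixed at binding time; stepping advances only its x
coordinate.  (The source model specifies only the head's x coordinate;
placing the head on the nearest surface line is this package's 3-D
embedding and makes the binding-eligibility distance and the tether
length agree at the moment of binding.)

## Forces

* **Tether**: zero for L = |A⃗ − H⃗| ≤ L_mot; Hookean with stiffness
  k_mot beyond, directed along the tether.  The force *on the cargo*
  points from anchor to head; the force on the head is its negative.
  A motor is under *hindering* load when the head-force x-component is
  negative (assistive when positive; exactly zero x with non-zero
  magnitude is classed hindering, a measure-zero conservative choice).
* **Steric**: when the centre-to-axis distance drops below R + r_MT, an
  outward radial spring of constant 10 k_mot acts in the y–z plane.
* **External**: none, a constant −x force f_h, or a harmonic optical
  trap (default isotropic 3-D; an x-only switch exists because the
  experimental geometry does not determine it).

## Dynamics (one timestep Δt)

The update order is: (1) motor kinetics using the forces at the start of
the step, (2) force recomputation, (3) anchor surface diffusion, (4)
cargo translation, (5) cargo rotation.  All orderings agree to O(Δt).

1. **Binding**: an unbound motor whose anchor is within L_mot of the MT
   surface binds with probability 1 − exp(−π0 Δt); the head is placed at
   the anchor's axial projection (zero initial strain — deterministic
   and testable; the alternative of a random reachable position differs
   only by a sub-rest-length transient).
2. **Stepping and detachment**: a bound motor attempts an 8-nm step with
   probability p_step = 1 − exp(−v Δt/δ), where v = v0([ATP]) ṽ(F);
   v0 is Michaelis–Menten in ATP and ṽ is 1 − (F/F_s)^w for hindering
   loads below stall (0 at stall) and 1 for assistive loads.  A motor
   can detach only while attempting a step, with per-attempt probability
   min(1, ε_micro Δt), ε_micro = ε_obs(F)/p_step(2 mM, F), so that the
   *net* detachment rate at saturating ATP is exactly the observed law
   ε_obs (exponential in F for hindering loads, linear for assistive
   ones, both evaluated at the full force magnitude |F⃗|).  At stall the
   construction is 0/0; the force factors cancel identically, leaving a
   Poisson detachment at rate ε_obs(F) · v0([ATP])/v0(2 mM), applied
   directly.  If ε_micro Δt exceeds 0.1 a warning flags the timestep as
   coarse for the forces encountered (transiently near stall this is
   expected and capped at 1).
3. **Anchor diffusion** (fluid cargo, D > 0): tangent-plane displacement
   √(2DΔt) ξ plus the drift (D/kT) F_tan Δt from the tangential
   components of the motor force, applied in the local spherical basis
   and followed by radial re-projection onto the sphere (bias
   O(Δl²/R), negligible at Δt = 1 μs).  At the coordinate poles
   (|sin θ| < 1e-6) a fixed tangent pair is used.
4. **Translation**: Euler–Maruyama with drag γ_c = 18πη_v R (as
   specified by the source model; deliberately not replaced by the
   Stokes 6πηR) and thermal noise √(2kTΔt/γ_c) per component.  Anchors
   translate rigidly with the centre.
5. **Rotation** (optional): the torque Σ r⃗_i × F⃗_i over bound motors
   divided by γ_R = 8πη_v R³, plus a stochastic angular step of fixed
   magnitude α√(4 D_R Δt) along a uniformly random direction, composed
   via the Rodrigues matrix and applied to the anchors and to the stored
   body frame.  The single-direction noise convention is kept exactly as
   specified; α absorbs the convention factor.

A run starts with the cargo at contact height, anchors uniform on the
sphere rigidly rotated so that one randomly chosen anchor sits at the
bottom, that motor bound without strain, and ends when every motor has
detached or at `max_time` (120 s default; runs cut by the cap are
reported as censored lower bounds).  A (seed, configuration) pair fully
determines every output; ensembles derive per-run child seeds from the
master seed.

Default Δt = 1e-6 s sits a factor ≈4.4 below the stiffest relaxation
time γ_c/(10 k_mot); the validator rejects timesteps above the bound
with a safety factor of 4.  Data are sampled at 100 s⁻¹.

## Rotational calibration (α)

For a fluid cargo α = 1 (free-sphere rotational diffusion D_R = kT/γ_R
≈ 10.3 rad²/s at R = 250 nm).  For a rigid cargo the noise amplitude is
calibrated so that a simulated one-motor tethered cargo reproduces the
experimentally reported 7×10⁻² rad²/s.  The estimator simulates the full
translational+rotational dynamics with one permanently bound,
non-stepping motor, accumulates the chord mean-square displacement of a
body-fixed axis over lag times, and fits a line with a free intercept
over lags 0.4–2.4 s; the reported diffusivity is slope/4.  The free
intercept matters: at short lags the apparent axis motion is dominated
by translation-coupled rolling about the tether point (an α-independent
contribution of order 0.1–1 rad²/s), which the intercept absorbs as a
plateau.  `calibrate_alpha` bisects α against this estimator on its
rising branch (at large α the axis decorrelates inside the lag window
and the apparent slope falls again, so the bracket defaults to
[1e-3, 0.3]).  The α-response is shallow near the target (the
tether-rolling contribution alone gives ≈0.057 rad²/s), so a
common-random-numbers bisection root carries a seed bias of order the
estimator noise; the shipped constant `ALPHA_RIGID` = 0.084 is the root
of the *seed-averaged* response (validated over eight independent
estimator seeds).  Re-measuring with the shipped constant is the
acceptance check.  The estimator's Monte-Carlo SEM is ≈0.0125 rad²/s at
the default budget (6 replicas × 30 s) and ≈0.005 at 12 × 30 s; the
test tolerance uses the default-budget value.

## Analytic run-length layer

The team run length is estimated by
r = v0/(N_a π_ad) [(1 + π_ad/ε_m)^{N_a} − 1], generalized to fluid
surfaces through the access area S_a (sphere surface within L_mot of the
MT surface; 1-D Simpson quadrature over the polar angle, converged to
1e-4), the influx area S_I (geodesic band of width √(2Dτ) around the
access area, computed on a boundary-distance grid and clipped at
S_T − S_a), N_a = 1 + (N−1)(S_a + S_I)/S_T and
π_ad = π0 S_a/(S_a + S_I).  The formula is validated against an exact
Gillespie birth–death simulation for integer N_a — the central
correctness property of the module.  The rigid-cargo weighted estimate
conditions on the initially bound motor and takes the remaining N−1
anchors as Binomial(N−1, S_a/S_T) members of the access area, each
evaluated with π_ad = π0.  Timescales use τ_off = v0(2 mM)/(ε0 v0([ATP]))
(detachment is gated by stepping attempts, hence the ATP rescaling) and
τ_bind = 1/((N_a−1) π_ad); the five standard (N, ATP) scenarios then
classify exactly as observed: fluidity lengthens runs iff
τ_bind < τ_off.  The bound/estimate construction uses the two measured
mean off-rates (0.12 s⁻¹ rigid, 0.10 s⁻¹ fluid at N = 4, 4.9 μM) and the
cargo heights at one and two bound motors; its upper bound takes all N
motors available at the n = 2 height.  The layer targets the
construction itself, not any particular published curve values.

## Synthetic-trajectory generator

`make_synthetic_trajectory` produces Markovian bind/unbind event trains
(per-motor exponential waiting times, optionally with permanently bound
motors), piecewise-linear cargo motion while ≥1 motor is bound, and
optional Gaussian sampling noise, in the same containers the simulator
emits.  Every estimator (off-rate, conditional on-rate, occupancy,
run length, windowed velocity, force statistics on hand-built force
tables) is required to recover the generator's parameters within three
standard errors.  The generator emulates the *statistical* structure of
the event stream, not the mechanics: it contains no forces, no geometry
and no thermal noise in z, so estimator tests validate the estimators,
not the physics; the physics is validated by the dynamical invariants
(diffusion laws, equipartition, detachment-time distributions) and the
headline ensemble statistics.

## Problem sizes and study conditions

Production-scale results in the source study use 200-run ensembles.
The shipped tests and `scripts/acceptance.py` use reduced ensembles
chosen so each check resolves its stated tolerance: 30 runs for the
N = 16, 2 mM run-length/stiffness/velocity ensembles (SEM ≈ 0.4 μm on a
2 μm mean), 16–20 runs for the fluid N = 16 ensemble, and low-ATP N = 4
ensembles grown until ≥150 completed motor engagements (the off-rate
SEM then resolves the 0.02 s⁻¹ rigid/fluid gap only at ~1 SEM, so those
checks use two-SEM bands around each value plus the ordering).  The
fixed-height on-rate experiment integrates the anchor's free diffusion
with its own coarser timestep (1e-5 s); the error there is set by the
ratio of the step length (~4.5 nm) to the access-region scale (~70 nm),
not by any spring stiffness.  Windowed velocities use δt = 0.1 s windows
and only (D, n) cells with ≥100 windows; per-window noise is dominated
by free cargo diffusion (σ_v = √(2 kT/(γ_c δt)) ≈ 2.4 μm/s), so cell
deviations are judged net of two cell SEMs.

## Known limitations

* Motor number is fixed per run (no exchange with solution) and runs end
  at full detachment; there is no rebinding from bulk.
* No MT lattice, no site exclusion, no motor–motor steric interactions,
  no backstepping, and no cargo deformation (the steric spring is stiff).
* The assistive off-rate grows linearly in the *full* force magnitude;
  for near-radial tether forces whose x-component sign flips thermally
  this is a harsh convention, and it makes clustered-motor survival in
  an optical trap sensitive to whether cargo rotation is enabled (the
  trap comparisons therefore follow the standard protocol with rotation
  on).
* The α calibration is a package-defined estimator (window, axis and
  intercept choices documented above); only the calibrated value's
  self-consistency is checked against the published target.
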