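# fluidcargo

Brownian-dynamics simulation of spherical-cargo transport along a
microtubule by teams of kinesin-1 motors, with tunable cargo-surface
fluidity.

## The scientific problem

Intracellular cargoes — vesicles, organelles — are hauled along
microtubules by small teams of kinesin motors.  Motors coupled through a
*rigid* cargo mechanically interfere: simultaneously bound motors pull
against each other, individual loads grow, and the force-dependent
detachment rate ε(F) rises, so teams detach sooner than independent
motors would.  A *fluid* (lipid) cargo surface lets the motor anchor
points diffuse, which relaxes inter-motor strain, improves load
sharing, recruits motors into the region from which they can reach the
filament, and can lengthen cargo run lengths several-fold at low ATP or
high motor number.

`fluidcargo` implements a 3-D overdamped Langevin model of this system
for quantitative study:

* cargo translation:  X⃗(t+Δt) = X⃗(t) + (Δt/γ_c)[Σ F⃗_j + F⃗_steric +
  F⃗_ext] + √(2kTΔt/γ_c) ξ⃗,  with γ_c = 18πη_v R;
* cargo rotation from the motor torque τ⃗ = Σ r⃗_i × F⃗_i and a
  stochastic angular step α√(4D_RΔt) n̂, composed with Rodrigues
  rotations;
* anchor surface diffusion in the local tangent plane,
  Δl⃗ = √(2DΔt) ξ⃗ + (D/kT) F⃗_tan Δt, re-projected onto the sphere;
* motor mechanochemistry: Hookean tether beyond the 57-nm rest length,
  Michaelis–Menten ATP dependence of the speed, force–velocity factor
  1 − (F/F_s)^w up to stall, stepping-gated detachment reproducing
  ε_hind = ε0 e^{F/F_d} and ε_asst = ε0 + 1.56 F s⁻¹/pN;
* binding at rate π0 = 5 s⁻¹ whenever the microtubule is within reach
  of the anchor.

An analytic layer evaluates the generalized multi-motor run-length
formula r = v0/(N_a π_ad)[(1 + π_ad/ε_m)^{N_a} − 1] with the available
motor number N_a = 1 + (N−1)(S_a+S_I)/S_T built from the geometric
access area S_a and the diffusive influx area S_I = band of width
√(2Dτ), and validates it against an exact Gillespie birth–death
simulation.  See `docs/methods.md` for the full model description.

## Worked example

Simulate a 30-run ensemble of rigid cargoes with 16 kinesins at
saturating ATP (2 mM), the configuration in which a 250-nm cargo runs
only about 2 μm despite its 16 motors, because only ≈1.4 of them can
reach the microtubule at any time:

```python
import fluidcargo as fc
from fluidcargo import observables as obs, analytic

params = fc.default_kinesin_parameters().with_overrides(
    cargo={"rotation_enabled": False},     # free-transport protocol
    run={"max_time": 60.0, "record_anchors": False,
         "record_orientation": False},
)
runs = fc.run_ensemble(params, 30, seed=1)
trajs = [t for t, _ in runs]

mean, sem = obs.mean_run_length(trajs)
print(f"mean run length {mean/1000:.2f} +/- {sem/1000:.2f} um")

H = obs.mean_cargo_height(trajs, n=1)
frac = analytic.access_area_fraction(H, 250.0, 57.0, 12.5)
print(f"one-motor cargo height {H:.0f} nm -> N_a = {1 + 15*frac:.2f}")

off = obs.off_rate_estimate([ev for _, ev in runs])
print(f"single-motor off-rate {off['off_rate']:.2f} +/- {off['sem']:.2f} /s")
```

prints

```
mean run length 3.90 +/- 1.61 um
one-motor cargo height 284 nm -> N_a = 1.47
single-motor off-rate 1.10 +/- 0.05 /s
```

The run-length distribution is heavy-tailed, so a 30-run mean carries a
large standard error; it is statistically consistent with the ≈2 μm
scale (larger ensembles converge there — `scripts/acceptance.py`
recomputes it).  The effective available-motor count N_a is ≈1.5 of 16;
and the measured per-motor off-rate (1.1 s⁻¹) sits well above the
unloaded ε0 = 0.79 s⁻¹ — the signature of negative interference on a
rigid cargo.  Re-running with
`motor={"surface_diffusion": 1.0}` (a fluid surface, D = 1 μm²/s)
lowers the off-rate and raises the bound-motor count.

The same machinery is scriptable from the command line:

```sh
fluidcargo ensemble --runs 30 --seed 2024 \
    --set cargo.rotation_enabled=false --out out/
fluidcargo analyze --ensemble-file out/ensemble.h5 --out out/report.json
fluidcargo theory --n 4 --out out/theory.json
```

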