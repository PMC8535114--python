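# Methods

`capsnav` simulates the two halves of an actively navigated magnetic capsule
endoscope at desk scale: the electromagnetic actuation (EMA) chain that turns
an operator's (yaw, pitch, push) command into coil currents, and the
localization chain that recovers the capsule's 5-DOF pose from a mono-axis
Hall-sensor board while the coils are active.  This note records the models,
the defaults and why they were chosen, and what the simulation does and does
not claim about a physical system.

## Capsule magnet model

The capsule carries an axially magnetized NdFeB cylinder (Ø10 mm x 12 mm,
grade N54).  At sensor distances of 10–50 mm — one to several magnet lengths —
it is modelled as a point dipole with moment m = M_s V along the capsule axis
D.  The field constant

    BT = mu0 |m| / 4 pi  ≈ 1.11e-7 T·m³

follows from a catalogue-typical N54 remanence of Br = 1.48 T
(M_s = Br/mu0 ≈ 1.18e6 A/m, |m| ≈ 1.11 A·m²).  The remanence is a datasheet
value, not a measured one, and is configurable.  A grid-of-elementary-dipoles
oracle in the test suite shows the point model within 1% of the finite
cylinder beyond 60 mm; closer in, the error grows but remains irrelevant to
the estimator, which fits the *same* model that synthesizes the data.
Near-field multipole corrections, demagnetization and temperature drift are
out of scope.

Steering and propulsion follow the magnetostatic laws τ = V M x B and
F = V (M·∇) B.  Gradient tensors are stored with G[i, j] = dB_j/dx_i, so the
force is V|M| Gᵀ D; in free space G is symmetric and traceless and the
transpose is cosmetic.

## Coil field basis and actuation

Each of the ten coils is an air-core filament stack: circular loops use the
exact elliptic-integral solution (on-axis closed form as a special case),
rectangular loops the four-segment finite-wire formula
B = (mu0 I/4π)(|r1|+|r2|)(r1 x r2) / (|r1||r2|(|r1||r2| + r1·r2)).
Inductance, eddy currents and amplifier dynamics are not modelled; currents
are what the allocator says they are, instantly.

The default layout is declarative and overridable from config:

| coils | geometry | purpose |
|---|---|---|
| Helmholtz pair, axis z | R = 0.25 m, sep = R, 500 turns | uniform Bz; differential drive gives dBz/dz |
| Maxwell pairs, axes x and y | R = 0.25 m, sep = √3 R, 500 turns | Bx, By and the diagonal gradients |
| rectangular pairs | 0.30 x 0.20 m, 300 turns, on the horizontal diagonals, one tilted 30° out of plane | cross-gradient (off-diagonal) components |

The off-axis mounting of the rectangular pairs is deliberate: every coaxial
pair aligned with a coordinate axis produces a purely diagonal gradient
tensor at the symmetry point, so a fully axis-aligned ten-coil set cannot
realize cross-gradient components there and the 6x10 actuation matrix drops
rank exactly where the workspace is centred.  With the diagonal mounting the
condition number of X(P) stays near 10 across the whole
100 x 100 x 40 mm ROI and a 5 mT / 50 mT/m set-point costs at most ~11 A per
coil on the default scenario, with brief ~25 A excursions at the far ROI
edge (declared limit ±30 A, exceeded with a warning, never silently
clamped).  The absolute field-per-ampere of the reference hardware
is not public, so only field *shapes* and requested set-points are
meaningful, and those the allocator achieves by construction.

The actuation matrix stacks, per unit coil current, the three field
components and the three heading-projected gradient components at the
capsule position.  Currents are the minimum-norm solution
i = X⁺ [B; F]_desired via SVD with a relative singular-value cutoff of
1e-10; rank deficiency is reported in diagnostics rather than masked.  The
command mapping expands (yaw y, pitch p, push F) into field γF·u(y, p) and
gradient F·u(y, p) along the commanded heading with the fixed ratio
γ = 0.1 m (the 1:10 tesla to tesla-per-metre pairing found to keep the field
uniform enough for stable control); gradient tensors use central differences
with step 1e-4 m.

## Localization

The sensor board is a 6x6 grid of mono-axis ratiometric Hall sensors
(20 mm pitch, spanning 100 x 100 mm at z = 0, measuring the global
z-component), modelled after the DRV5055: 12.5 mV/mT about a 2.5 V midpoint,
±169 mT range, 16-bit acquisition over 0–5 V.  The quantization step is
therefore ~6 µT, below the 50 µT default noise floor.

With the coils active each sensor reads the superposition HS = HM + HEMA.
Compensation subtracts the reconstructed actuation field using the
unit-current basis at the sensor positions and the currents at read time —
no coil geometry knowledge is needed beyond the basis table itself, which in
hardware would be a measured database and here is computed from the same
coil model (exact cancellation by construction on synthetic frames; a
mis-scaled basis leaves proportional contamination, quantified in tests).

The estimator fits the dipole z-field model to the compensated readings by
Levenberg–Marquardt over five parameters (x, y, z, yaw, pitch).  Roll of an
axially magnetized capsule is unobservable and is not a parameter;
parameterizing the heading by yaw/pitch removes the unit-norm constraint
that makes the naive six-parameter (a, b, c, m, n, p) Jacobian singular.
Heading *polarity* is observable (flipping D negates every reading), so no
disambiguation step is needed.  Numerical choices:

* MINPACK LM via `scipy.optimize.least_squares(method="lm")`,
  xtol = ftol = gtol = 1e-14, up to ~200 iterations;
* candidate positions are kept at least 5 mm above the board by a smooth
  linear penalty below the floor, with a bounded trust-region refinement
  pass in the rare case the unconstrained minimizer ends below it
  (MINPACK LM itself takes no bounds);
* warm start from the previous frame during tracking; cold start from the
  lowest-cost cell of a 10 mm position grid crossed with six planar
  headings;
* saturated sensors are dropped (at least 6 of 36 must remain for
  5-DOF identifiability, and that many remain in every scenario shipped);
* the covariance proxy is s² (JᵀJ)⁻¹ from the final Jacobian — a linearized
  uncertainty indicator, not a calibrated posterior.

At pitch ±90° the yaw is undefined (gimbal degeneracy of the
parameterization); the inverse map flags it and returns yaw 0.  The tracking
scenarios stay far from the pole.

## Synthetic data and plant dynamics

`synth_sensor_frame` produces exactly what the acquisition chain would hand
the estimator: dipole z-field + actuation field + i.i.d. Gaussian noise per
sensor (default σ = 0.05 mT, standing in for sensor noise, residual
calibration error and ambient variation), clipped to the range and
quantized.  One seeded generator per run; identical seeds give bit-identical
logs.

The plant is quasi-static and overdamped, matching the manipulation regime
of a capsule in viscous or frictional media: no inertia, terminal velocity
v = max(0, (|F| − F_friction)/c_drag) along the net force, and first-order
heading relaxation toward the local field direction with time constant
τ_align · (5 mT / |B|), so weak fields align proportionally slower (torque
scales with |B|).  Defaults: τ_align = 0.05 s, c_drag = 2.2 N·s/m (chosen so
the free-space preset moves at ~25 mm/s, a deliberate capsule speed),
friction threshold 0 in free space.  In tube mode velocity is projected on
the local centerline tangent and the position clamped to the tube radius.
Peristalsis, tether drag, rolling and organ deformation are not modelled;
the noise term is the lumped surrogate.

The closed-loop controller replaces the joystick operator with a
waypoint-seeking proportional policy using the same three controls: at
20 Hz, estimate the pose (warm-started), aim yaw/pitch at the next waypoint,
push with the preset gradient (free-space 5 mT / 50 mT/m; phantom preset
7 mT / 70 mT/m), advance waypoints inside a 5 mm capture radius, and slow
down proportionally within the last capture radius to stop within 1 mm of
the endpoint.  The control frequency, capture criteria and policy are this
package's stand-ins — the reference system used a human operator and states
none of them.

A note on the field:gradient ratio: in this rigid free-space plant with a
20 Hz computer-in-the-loop allocator, halving γ to 0.05 m does *not* degrade
tracking — the physical penalty of ratio misuse is dominated by
organ-deformation effects and operator-scale command latency, both outside
this model.  The instability the ratio guards against does appear here once
the aligning field becomes genuinely inadequate (mean error grows ~6x by
γ = 0.002 m), and that regime is what the property test exercises.

## Experiment presets and problem sizes

* **Tracking trials**: 4 seeded repeats of the U-shape scenario (80 mm
  extent, 5 mm waypoint spacing, ~146 control ticks ≈ 7.3 s each), reporting
  per-trial mean/SD/max of (a) the perpendicular 2D distance of the true
  position to the desired polyline — the headline "movement error", planar
  because the trial is a top-view planar manoeuvre — and (b) the
  estimated-vs-true localization error.  Typical results: mean path error
  ≈ 0.28 mm, localization error ≈ 0.1 mm, well inside the reference
  hardware's 1.91 mm first-trial mean — as expected, since the simulation
  omits tether stiffness, rolling and field distortion at the ROI edge,
  which dominate the physical error budget.
* **Recovery study**: 500 random poses over the ROI (z in 10–40 mm,
  pitch within ±60°), frames synthesized per noise level, estimates started
  from a truth-offset init emulating tracking warm starts.
* **Acceptance script** (`scripts/acceptance.py`): recomputes the four-trial
  scenario from scratch at a given base seed and writes the first-trial mean
  and the four-trial maximum mean error in mm.

Problem sizes were chosen so the full suite runs in a few minutes on one
core while keeping every statistic stable to well under the margins it is
compared against.

## Known limitations

The simulation validates the *algorithms* — allocation, compensation,
estimation, closed-loop integration — not the hardware physics: coil
constants are representative, the compensation basis is computed rather than
measured (so basis error enters only through the deliberate perturbation
studies), and the plant omits every tissue-interaction effect.  Passing
tests therefore demonstrate internal consistency and algorithmic
correctness under a realistic noise model, not field performance of a
physical system.
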