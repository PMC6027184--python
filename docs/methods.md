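# Methods

## Model overview and assumptions

The elbow is modelled as three rigid bones — humerus, ulna, radius — with no
kinematic joints: assembled, the system has 18 rigid-body degrees of freedom
and zero constraint equations. Joint behaviour emerges from three passive
force systems plus muscle actuation:

1. **Ligaments.** Fourteen tension-only bundles (MCL anterior ×3, MCL
   posterior ×3, LUCL ×3, RCL ×3, annular ×2). Each bundle is an elastic
   spring in engineering strain ε = (l − l₀)/l₀ with a parabolic toe region
   f = ¼kε²/ε_l for 0 ≤ ε ≤ 2ε_l blending C¹-continuously into the linear
   branch f = k(ε − ε_l); slack bundles carry nothing. The toe parameter
   defaults to ε_l = 0.03. Bundle paths run origin → via points → insertion;
   any segment that penetrates an analytic wrap obstacle (sphere or
   cylinder) is replaced by the closed-form tangent–arc–tangent geodesic
   (cylinders unroll, so length = hypot(planar path, axial offset)).
   Ligaments are purely elastic — no viscoelasticity, no failure, and no
   joint capsule.
2. **Cartilage contact.** The humeral articular cartilage is tiled into
   quadrilateral elements of ≈3 × 3 mm (the default `target_size`); each
   element stores its true area, area-weighted centroid and outward normal.
   An element penetrating the opposing surface by δ along its normal
   produces a frictionless normal force Fc = k_c δⁿ + B_c(δ) δ̇ with
   k_c = 40 N/mmⁿ, n = 3.05, and damping ramping smoothly (cubic smooth-step)
   from 0 to c_max = 5 N·s/mm at d_max = 0.1 mm; the total is clamped at ≥ 0
   so damping can never act as adhesion. Contact is evaluated at element
   centroids, applied along element normals, with the equal-and-opposite
   reaction on the opposing body at the same point. Three articulations use
   this law (ulnohumeral, radiohumeral, proximal radioulnar), plus a distal
   radioulnar bearing (below).
3. **Muscles.** Six actuators (triceps long/lateral/medial, biceps
   long/short, brachialis) as polyline paths with fixed via points. During
   forward dynamics a discrete PID controller per muscle converts the error
   between current and recorded path length into a pulling force:
   rectangular integration, backward-difference derivative, output clamped
   to [0, F_max], and integral accumulation frozen while clamped
   (anti-windup — necessary because of the clamp, and harmless otherwise).
   The error sign convention makes a longer-than-target muscle pull. Gains
   scale linearly with PCSA: gain_i = (PCSA_i / 487 mm²) × global gain,
   global (P, I, D) = (50, 5, 0.0005). Activation/contraction (Hill-type)
   dynamics are out of scope.

## Two-phase protocol

*Inverse kinematics*: the recorded trial poses are replayed exactly (a
uniform time grid is required) and every muscle's length trajectory is
recorded; passive forces may be evaluated for reporting but cannot alter the
motion. *Forward dynamics*: the humerus is prescribed from the trial (motion
driver) while ulna and radius evolve freely under gravity, ligament, contact
and muscle forces; muscle forces come from the PID controllers tracking the
recorded lengths, linearly interpolated from the 100 Hz recording to the
integration step. The 18-DOF audit counts all three bodies before the driver
is applied. Initial state is the first trial frame with zero twists.

## Integration and numerical choices

- **Scheme.** Fixed-step semi-implicit (symplectic) Euler in momentum form:
  linear momentum and angular momentum about the COM (world frame) are
  updated from the accumulated wrenches, velocities are derived, then poses
  are advanced and quaternions renormalized. Integrating momentum rather
  than velocity makes torque-free angular momentum exactly conserved.
  Internal step 1e-4 s; outputs resampled to the 0.01 s reporting step.
- **Units.** mm, kg, N, N·mm, MPa (N/mm²); gravity 9810 mm/s²; energies in
  N·mm. Bone density 1600 kg/m³, cartilage 1000 kg/m³.
- **Contact sub-stepping.** The contact law hardens steeply with depth
  (∝ δ^2.05 in stiffness), and the bones are light (tens of grams), so the
  engaged-contact frequency can exceed what the base step carries. Each
  outer step is subdivided so that (a) the linearized contact frequency —
  translational plus rotational, the latter mattering because the slender
  bones have kg·mm²-scale inertias about their long axes — stays below
  ω·Δt ≈ 0.3, and (b) penetration cannot change by more than 0.02 mm per
  sub-step. The initial contact state is primed before the first step so a
  noisy first frame is already sub-stepped.
- **Damping limiter.** The printed contact damping (5 N·s/mm per element) is
  orders of magnitude beyond what an explicit step can carry for gram-scale
  bones, and its torque about a slender bone's long axis is stiffer still.
  Each element's damping coefficient is therefore capped so the viscous
  impulse per step cannot exceed half of what would annihilate the pair's
  relative momentum along that element's normal, using the full effective
  mass (translational + rotational, via the contact lever about the COM).
  The cap preserves strict dissipativity; the full printed coefficient
  applies whenever the step can carry it (it shrinks as sub-steps shrink).
- **Soft-tissue drag.** With elastic-only ligaments and frictionless contact
  the bones-only model has almost no dissipation outside the contact normal
  direction, and millimetre-scale joint rattle persists indefinitely. A
  small explicit viscous drag on free bodies (0.02 N·s/mm on the COM
  velocity, 2 N·mm·s on the angular velocity) stands in for peri-articular
  soft-tissue dissipation. At tracking speeds it contributes only a few
  N·mm of bias torque, which the integral term absorbs. Both coefficients
  are model parameters and are set to zero in conservative-energy studies.
- **Divergence guards.** Non-finite wrenches, |v| > 10⁶ mm/s,
  |ω| > 10⁴ rad/s, or penetration beyond 5 mm raise a solver error naming
  the step and element.
- **Energy accounting.** Total energy = kinetic + gravitational + closed-form
  ligament elastic energy + contact elastic energy k_c δⁿ⁺¹/(n+1). For a
  symplectic integrator the meaningful diagnostic is the windowed-mean
  (secular) drift; the instantaneous energy oscillates within a bound
  proportional to ω·Δt.

## Geometry and discretization

Mesh I/O goes through trimesh (binary/ASCII STL and OBJ), with a unit hint
scaling to millimetres. Cartilage tiling auto-detects the surface chart from
the area-weighted distribution of face normals: zero spread → planar chart
(grid axes from the dominant in-plane direction, falling back to projected
world axes when the patch is isotropic, so axis-aligned patches tile
predictably); normals orthogonal to a common axis → cylindrical chart
(u = axial, v = unrolled arc, branch cut in the largest angular gap);
otherwise spherical (Lambert azimuthal equal-area about the cap pole).
Triangles are recursively subdivided below a quarter of the element size and
binned by sub-centroid, so the element areas sum exactly to the mesh area
and border elements keep their true, smaller areas. Element thickness is a
stored constant (2 mm default) used only for bookkeeping/visualization.
Penetration against closed meshes uses parity containment plus
Möller–Trumbore ray casting along the element normal (no external spatial
index); the congruent synthetic joints use closed-form concave sockets
(cylindrical and spherical) instead, which are exactly consistent with the
primitive surfaces they oppose.

Anatomical frames follow a fixed convention: ML from the lateral to the
medial epicondylar landmark (+ML medial for a right arm), SI the
orthogonalized shaft direction (+SI proximal), AP = SI × ML (+AP anterior),
origin at the epicondylar midpoint. Kinematic decomposition uses the
body-fixed sequence F–E (about humeral ML) → VR–VL → I–E; translations are
the child frame origin in the humerus frame. A varus–valgus angle near 90°
triggers a gimbal-proximity warning but still returns values.

## Calibration

Zero-load lengths are estimated from the passive laxity sweep: per bundle,
l₀ = 0.8 × the maximum wrapped path length over the sweep (the straight-line
option exists behind a flag; the wrapped path is the default since wrapping
is part of the length model everywhere else). The 0.8 factor compensates the
small stretch the examiner imposes; it is a single global value, overridable
per bundle because a constant factor is known to over-tighten some bundles.

## Synthetic subject

The generator stands in for an MRI-derived subject and emulates the study
conditions: congruent analytic articular surfaces (trochlear cylinder of
12 mm cartilage radius over 320°, capitellar sphere of 10 mm, matching
ulnar/radial sockets), 14 bundles at anatomically inspired sites with the
LUCL wrapping the radial head, Holzbaur-type muscle PCSA/F_max (their mean,
490 mm², is consistent with the 487 mm² reference), bone masses from shaft
volumes at the stated densities (humerus ≈ 0.14 kg, ulna ≈ 0.077 kg, radius
≈ 0.057 kg). Two deliberate departures from strict anatomy keep the
passive skeleton mechanically complete without a joint capsule or
interosseous membrane: the radial-head dish aperture extends 15° past the
equator (the annular hood's grip), and a distal radioulnar ring bearing at
200 mm slaves the radial shaft to the ulna — the role the interosseous
membrane plays — while leaving pronation free. Trials: isokinetic ramps at
10 and 60 deg/s with 0.2 s raised-cosine velocity blends, a "free" trial
with a raised-cosine velocity profile peaking at 300 deg/s, and a laxity
sweep covering the 10–100° flexion range with ±6° varus–valgus and
internal–external excursions. All poses carry seeded Gaussian marker-like
jitter (0.2 mm / 0.2° per frame, 100 Hz); EMG surrogates are sampled at
1400 Hz.

The surrogate EMG is a seeded Rademacher (±1) carrier — zero-mean and
spectrally flat, with unit magnitude so that rectification returns the
envelope itself — amplitude-modulated by the normalized muscle-force
envelope band-limited to 2 Hz (volitional force envelopes at these movement
speeds live well below that; the band limit represents activation dynamics
smoothing the controller's fast force fluctuations), plus a 1 % broadband
baseline. What the synthetic data do **not** emulate: anatomical mesh
irregularity, soft-tissue artefact structure (noise is white, real marker
artefact is correlated), EMG spectral shape and cross-talk, and population
variability. Passing tests therefore demonstrate internal consistency of
the machinery under realistic magnitudes, not agreement with any real limb.

## Problem sizes used in the test suite

The closed-loop check runs the full synthetic 60 deg/s trial (≈3.4 s of
motion at a 1e-4 s internal step with adaptive sub-stepping). The
conservative-energy check integrates a two-body ligament suspension for 10 s
at 1e-4 s with soft test springs (k = 10 N/strain) so the suspension
frequency sits far below the step limit and the symplectic energy bound is
itself informative. The free-rotor check runs 10 s at 1e-4 s. These sizes
were chosen as the smallest runs that exercise every regime (settling,
steady tracking, reversal) of the method.

## Known limitations

- The kinematic channels orthogonal to flexion (VR–VL, I–E) sit at the
  scale of passive laxity plus injected noise and decorrelate from the
  reference — expected for a hinge-free joint, and mirrored in how such
  models compare against experiments, but it means those channels are not
  meaningful accuracy metrics here.
- The taut calibration (l₀ at 80 % of the observed maximum) preloads the
  joint; forward dynamics settles ≈0.5 mm away from the kinematic reference,
  a constant translation bias visible in the ML/AP channels.
- Muscle paths are polylines without smooth wrapping; moment arms are
  therefore only piecewise-smooth in deep flexion.
- The feedback controller cannot produce force without length error, so
  co-contraction and isometric force are outside the model.
- The explicit integrator trades the full printed contact damping for a
  stability-capped value during violent transients; steady-state contact is
  unaffected.
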