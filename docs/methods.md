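# Methods

`runopt3d` predicts and reconstructs periodic 3D running motions by
trajectory optimization of a muscle-driven skeletal model with implicitly
formulated dynamics. This note documents the model, the transcription, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## Skeletal model

The built-in *reduced runner* is a 3D rigid-body tree with 21 degrees of
freedom: a six-DOF pelvis root (three translations; rotations ordered
heading–list–tilt with heading about the vertical axis outermost), a
three-DOF torso joint, and per leg a ball-and-socket hip, revolute knee,
revolute ankle and revolute subtalar joint. The coordinate convention is x
forward, y up, z to the subject's right; placing the heading rotation
outermost makes the rotational-symmetry constraint of curved running act on
a single coordinate. Segment masses, lengths and inertias scale with
standard anthropometric fractions of subject mass and height (fractions sum
to one, so segment masses add up to the subject mass exactly); the default
subject is 92 kg and 1.95 m. The framework itself is generic: models are
plain data (segments, joints, muscles, contact points, bounds) serialized as
YAML, and all algorithms operate on that description, so a full-complexity
model can be dropped in without code changes.

The state vector is `x = (q, qdot, s, a)` and the control vector
`u = (n_e, m)`: generalized coordinates and rates, per-muscle contraction
state and activation, neural excitations, and the normalized torques of
three residual actuators at the torso (torque = 10 N·m × m, |m| ≤ 5).

## Muscles

Eighteen Hill-type muscle–tendon units (nine per leg) condense the main
lower-limb groups: iliopsoas, glutei, hip abductor, hip adductor,
hamstrings, rectus femoris, vasti, triceps surae (gastrocnemius and soleus
merged into one plantarflexor with a small knee-flexion and
subtalar-eversion arm) and tibialis anterior. Muscle–tendon length is a
polynomial in the spanned joint angles; moment arms are the negative length
gradients (virtual work). Strengths and arms were chosen so the model can
produce running-scale joint torques for a 92-kg subject (peak plantarflexion
≈ 520 N·m isometric, knee extension ≈ 360 N·m); the distal contact point
sits at the metatarsal heads, which keeps late-stance ankle moments in the
range the plantarflexors can deliver while shortening.

Contraction dynamics are implicit in the projected CE length `s` (CE length
projected onto the line of action), which stays smooth for pennation angles
up to π/2: with constant muscle height `h = l_opt sin(φ_opt)`,
`l_CE = sqrt(s² + h²)` and `cos φ = s/l_CE`. The residual balances the
tendon force against the projected CE force,

    F_SEE(l_MTU − s) − (a F_ISO f_L(l_CE) f_V(v_CE) + F_PEE + d_CE v_CE) cos φ = 0,

with a Gaussian force–length curve (width W = 0.56), a Hill force–velocity
hyperbola (v_max = 10 l_opt/s, shape 0.25, eccentric plateau 1.5, C¹ at
zero velocity), quadratic tendon (4 % strain at F_ISO) and parallel-elastic
elements, and a small CE damping d_CE = 0.01 F_ISO/(l_opt/s) that makes the
implicit ODE strictly monotone in `sdot` (unique solution, bounded
Jacobians). Activation follows a first-order ODE whose rate blends smoothly
between 1/T_act (= 1/0.01 s) and 1/T_deact (= 1/0.04 s) with excitation.
The positive-part functions in the tendon/PEE forces are smoothed with a
1e-4 strain half-width; this shifts forces by a few parts per million,
which the tests account for.

## Ground contact

Each foot carries two contact points (heel, metatarsal). The ground is the
plane y = 0 with a penetration law that is C¹ everywhere: smoothed
penetration `p = ½(√(y² + eps_p²) − y)` (eps_p = 1 mm), normal force
`k_n p³ (1 − c_n ẏ)` with the damping factor softly clamped at zero
(k_n = 2.5e8 N/m³, c_n = 1 s/m), and Coulomb friction regularized over a
slip-speed scale v_c = 1 cm/s (μ = 1). Smoothness everywhere is essential:
the optimizer must be able to differentiate through contact on/off and
stick/slip transitions.

## Objective

The total objective is `J = W_Track J_track + W_mus J_mus + W_tor J_tor +
W_reg J_reg`. Tracking averages squared deviations of the simulated signals
from the reference means, normalized by the measured variance floored at
10 % of each signal's mean variance (swing-phase GRF variance would
otherwise divide by ~0); per-signal weights form a weighted arithmetic mean
with W_ang = 1 and W_GRF = 5 and sum to one. Muscular effort is the
volume-weighted mean cubed excitation divided by the cubed horizontal speed
(divisor 1 for standing, where the reference speed is zero). The torque term
is the mean squared normalized arm/torso control. Regularization penalizes
mean squared backward-difference rates of all states and controls, wrapping
through the periodicity map. All integrals use the same backward-Euler
rectangle rule as the dynamics, so the 1/T normalization cancels into 1/N.

Task weights: standing W_mus = W_tor = 1; straight-running tracking
W_Track = 1, W_mus = 1e3, W_tor = 1; curved running multiplies the effort
and torque weights by ten. The regularization weight defaults to 1e-3: with
the dimensionless tracking scale of this package a larger value visibly
trades tracking quality for smoothness (at 0.1 the regularization dominated
the objective and suppressed the motion entirely), while 1e-3 leaves it one
to two orders below the tracking term at typical solutions.

## Transcription

Backward-Euler direct collocation on N nodes t_k = k h, h = T_sim/N, with
the cycle duration a decision variable. The state at T_sim is not a
variable: it is the periodicity image `R_per x₀ + t_per` of the first node,
giving exactly N defect blocks `f(x_k, (x_k − x_{k−1})/h, u_k) = 0` and
closing the cycle without duplicated variables; controls are identified
across the wrap. Straight running translates the pelvis position by
(v_x T, 0, v_z T); curved running rotates pelvis horizontal position and
velocity about the vertical axis by the central angle
θ = 2 asin(‖v‖T/2r) and adds θ to the heading, all other entries mapping
identically (the velocity-pair rotation is required for a rotationally
symmetric gait even though only position and heading define the map).
First-node anchors (pelvis tx/tz) are imposed by pinning those decision
variables. For the standing task there is one node, ẋ ≡ 0, the joint rates
are pinned at zero (implied by the kinematic identity rows) and no
periodicity applies.

Residual rows are nondimensionalized so one defect tolerance is meaningful
across units: multibody rows by subject weight, muscle-contraction rows by
each muscle's F_ISO, activation rows by T_act. The defect tolerance is
1e-3 in these units (≈ 0.9 N on force rows for the default subject).

## Dynamics evaluation and derivatives

The skeletal equations are evaluated in inverse-dynamics form by a
recursive Newton–Euler pass over the tree with every multi-DOF joint
decomposed into elementary one-DOF joints; the mass matrix is never formed.
Contact and muscle forces enter as generalized forces through point and
path Jacobians (virtual work). All code is vectorized over nodes and
written dtype-agnostically so that derivatives come from batched
complex-step differentiation (exact to machine precision). The per-node
residual Jacobians exploit structure — contraction/activation rows are
diagonal in (s, a, ṡ, n_e), the multibody rows' s-dependence is moment arm
× tendon-force slope — which cuts the complex-step batch from 178 to 67
directions; the structured fast path is unit-tested against the full
complex-step Jacobian to machine precision, and both against central finite
differences.

## Solving the NLP

With every objective term an exact sum of squares, the natural solver is
Gauss–Newton. The running problems are solved by an augmented-Lagrangian /
penalty continuation (penalty weights 100, 1000, 10000 on the defect rows,
with multiplier updates once near-feasible) whose inner iterations are a
projected Levenberg–Marquardt with exact sparse-LU solves of the normal
equations — the collocation Jacobian is narrow-banded, so direct
factorization is cheap and gives far better steps than Krylov
approximations on these ill-conditioned systems. A defect-only restoration
phase polishes the dynamics at the end. The single-node standing problem
uses the bounded trust-region least-squares path (scipy's TRF/LSMR), which
is robust for its size; at qdot = 0 the pelvis horizontal-force and heading
rows are consistent linear combinations of the kinematic-identity rows
(friction vanishes with slip speed), which rules out active-set QP solvers
that require full-rank constraint blocks.

Warm starts matter more than solver strength here. The standing task draws
its multistart guesses uniformly within bounds (pelvis translations within
an upright box) and keeps the best converged result. The running tasks
build their start from the standing solution plus the tracking reference:
joint angles and low-passed rates from the reference means; pelvis height
geometric during stance (stance-foot penetration matched to the tracked
GRF through the contact law, corrected once for the normal damping factor)
and ballistic across flight; fore-aft speed ripple by integrating the
tracked braking/propulsion force; muscle tendon forces distributed per node
by a bounded least-squares over moment arms to match the inverse-dynamics
joint torques, with contraction states and activations inverted from those
forces. Without the muscle part of this seed the Gauss–Newton model is
nearly blind to the excitation–force chain (at a = n_e = 0 the activation
rows are exactly satisfied and excitations only influence forces through a
long telescoping coupling), and the optimizer switches the muscles off.
The curved-running start bends the straight solution onto the circle
(positions on the arc, heading tangent, velocities rotated).

Known limitation: with these scipy-based solvers the running tasks do not
always reach the 1e-3 defect tolerance within a desk-scale compute budget;
the solution report always carries the achieved maximum defect and a
converged flag, and an unconverged solve is never silently accepted. The
task constraints themselves (prescribed speed, circle radius, chord and
heading relations) are enforced structurally by the anchors and the
periodicity image, so the reported task quantities are exact regardless of
the remaining defect. No minimal-distance or collision constraint is
imposed between segments; leg interpenetration in curved running is a known
property of this problem class, reproduced rather than fixed.

## Synthetic reference data

The generator emulates one subject's treadmill-style session: 12 noisy
realizations of a periodic gait cycle (right heel strike to right heel
strike, sampled at 200 Hz with slightly varying cycle lengths), linearly
resampled to the collocation grid and averaged into mean and SD per signal.
Cadence follows a stride-length rule L = 0.5 v + 0.8 m. Vertical GRF is a
smooth per-stance hump (duty factor 0.35) scaled so both feet's
cycle-average vertical force equals body weight exactly; fore-aft GRF is a
biphasic braking/propulsion shape with zero net impulse; mediolateral GRF
is a small hump with per-side sign. Sagittal joint angles come from a
rolling-contact plan — stance foot flat and stationary with late-stance
heel lift about the toe, swing foot on a smooth clearance path, pelvis
height from double integration of the planned GRF — passed through planar
two-link inverse kinematics and a 12-harmonic low-pass, so the angle data
are dynamically plausible (near-zero stance-foot slip, no ground
interpenetration). Non-sagittal angles are small sinusoids. Angle noise is
additive with constant pointwise SD (2° default); GRF noise is a
mean-centred multiplicative factor (5 %), which leaves swing-phase variance
at zero and exercises the tracking variance floor.

What this does not emulate: soft-tissue artifact, marker redundancy,
filtering effects, inter-subject variability, asymmetries, or measured
curved-running data (curved running is predicted from straight-running
data, as the task intends). Passing tests therefore demonstrate the
machinery — data preparation, transcription, derivatives, task constraints
— on realistic magnitudes, not fidelity to any particular subject.

## Problem sizes used in tests and acceptance runs

The shipped test suite and the acceptance script run the chain at
desk-scale sizes chosen as the package's default study conditions: 16–24
collocation nodes for the running tasks, 4–12 standing starts, with the
node-count consistency check at 25 vs 50 nodes warm-started from a common
coarse solution. Larger grids change only compute time, not the code path:
`N` is an argument everywhere.
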