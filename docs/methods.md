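# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order the pipeline runs.

## Planar musculoskeletal model

The skeleton is a five-segment planar chain: a floating pelvis (two
translations and a tilt), a torso segment (head, arms, trunk and the
contralateral leg lumped together) on a lumbar joint, and thigh, shank and
foot of the hopping leg on hip, knee and ankle joints — seven generalized
coordinates in total. Segment masses, lengths, centres of mass and
moments of inertia follow standard anthropometry scaled to a 79.9 kg,
1.82 m adult. Hip and knee flexion and ankle dorsiflexion are positive.
The lumbar joint exists so the idealised trunk torque actuator (max 300
N m, first-order excitation-activation dynamics with a 35 ms
electromechanical delay) has a degree of freedom to act on; it also
absorbs trunk counter-rotation during hopping.

Ten Hill-type muscle-tendon units (MTUs) actuate the leg: iliopsoas,
lumped glutei, lumped hamstrings, rectus femoris, three separate vasti
(lateralis/intermedius/medialis, kept separate so the quadriceps force
decomposition exists for the adaptation model), gastrocnemius, soleus and
tibialis anterior. Muscle paths are straight lines through via points
fixed in the segment frames; this gives an exact length/moment-arm oracle
for testing and an unambiguous line of action for the joint-reaction
analysis. Maximum isometric forces are plausible adult values scaled with
body mass; optimal fibre lengths and tendon slack lengths are derived at
model build time from the path excursion over the joint ranges of motion
(the fibre covers roughly ±30% of optimal length over the full range,
with the tendon taking up the remainder of the reference-pose length).
Maximum shortening velocity is 10 optimal fibre lengths per second.
Pennation uses the fixed-height (constant-thickness) fibre model.

The dimensionless Hill curves are of the standard forms: a sum of three
Gaussians for active force-length, a logarithmic force-velocity curve, and
exponential parallel-elastic and tendon curves, with a small fibre damping
term (0.1 normalised force per normalised velocity). Two deliberate
adjustments: the active force-length and force-velocity curves are
normalised so that f(1) = 1 and f(0) = 1 hold exactly (the raw published
coefficient sets miss these identities by a few parts per thousand, which
would make the isometric unit tests approximate for no benefit), and the
parallel-elastic curve is smooth-clamped at zero (softplus with a 1e-4
length scale) so passive force is non-negative while every curve stays
twice continuously differentiable. The tendon stiffness parameter is
calibrated by root finding so the normalised tendon curve has slope 35 at
4% strain.

## Contact and body-weight support

Foot-ground contact uses two spheres (heel and toe, radius 0.02 m) with a
Hunt-Crossley normal force `F = k·d^{3/2}·(1 + 1.5 c ḋ)` in which both
the penetration positive-part and the damping bracket are replaced by
C-infinity softplus smoothings (length scales 1e-5 m and 1e-2), so the
force and its first two derivatives are continuous through touchdown.
Tangential force is smooth Coulomb friction, `−μ F_n tanh(v/1.0)` with
μ = 0.8; the 1 m/s velocity scale makes the law near-viscous, a
deliberate choice because vertical hopping involves essentially no slip
and sharper laws turn millimetre-scale velocity noise into hundreds of
newtons of spurious shear. Body-weight support is a constant vertical force
`(1 − g_level)·m·9.81` applied at the pelvis centre of mass; gravity in
the dynamics is always terrestrial.

Rigid-body kinematics and inverse dynamics are evaluated in closed form
over the chain (world-frame positions/velocities/accelerations of every
segment, generalized forces from the inertial-minus-gravitational wrench
contracted with the coordinate Jacobians). An energy-rate oracle (power
of the generalized forces equals the rate of mechanical energy) guards the
implementation.

## Muscle geometry polynomials

Inside the optimal control problem, MTU lengths and moment arms are
degree-4 polynomials of the spanned coordinates, fitted by ordinary least
squares on 2000 uniform random poses over the ranges of motion extended by
20%. Moment arms are the exact analytic derivatives of the fitted length
polynomial (r = −∂L/∂q), so lengths, velocities and moment arms are
mutually consistent by construction; fits are rejected if the maximum
length residual exceeds 2 mm. Fitted sets are memoised on a content hash.

## Synthetic trials

The generator builds one periodic hopping cycle per condition and samples
it over ~2.4 cycles at 200 Hz (kinematics) and 2000 Hz (forces). Study
conditions: hop frequency 2 Hz; contact times per gravity level 0.29,
0.27, 0.28, 0.32 and 0.34 s for 0.17–1 g; five gravity levels; additive
Gaussian measurement noise of 0.5° on angles, 2 mm on pelvis translations
and 5 N on forces; per-trial contact-time jitter of 5 ms. Construction
order matters for consistency:

1. a squared-half-sine ground-penetration pulse with a smooth plateau
   (spring-like loading) is prescribed over the contact time (foot flat,
   equal penetration under both spheres); the recorded GRF **is** the
   contact-model force along that pulse, with the depth iterated so the
   vertical impulse balances the effective weight over the cycle exactly;
2. the whole-body centre of mass is obtained by integrating
   `m a = GRF + BWSS − m g` with periodic boundary conditions (flight is
   automatically ballistic at the effective gravity);
3. stance joint angles come from closed-form two-link inverse kinematics
   (pelvis placed so the COM follows step 2, ankle pinned by the
   penetration, foot flat), with the trunk leaning forward in proportion
   to the crouch depth (a hip-hinge strategy that keeps knee extension
   demands physiological); flight angles are quintic Hermite blends that
   match position, velocity and acceleration at lift-off and touchdown,
   plus a small knee-flexion bump (ankle counter-rotated) that guarantees
   ground clearance;
4. a fixed-point pass adds a torso (lumbar) counter-rotation, integrated
   exactly in the Fourier domain, that absorbs the residual root moment.

The result is dynamically consistent to within a few tens of N m of
root moment before noise (the tracking problem absorbs the remainder). The generating contact parameters are a stiffness of 5.0e5
N m^-3/2 and damping of 1.0 s/m — a compliant shoe/mat interface with
centimetre-scale penetrations. Softness here is a deliberate condition:
with a very stiff contact, millimetre-level changes introduced by the
6 Hz measurement filter translate into force errors of hundreds of
newtons, and no dynamically consistent trajectory can track both the
filtered kinematics and the filtered GRF; the compliant interface keeps
that irreducible inconsistency well inside the acceptance bands. The
stiffness deliberately differs from the optimiser's 1e6 starting guess so
parameter identification is a real test. Touchdown posture deepens with
gravity (knee flexion at touchdown 0.35 + 0.55·g_level rad), reproducing
the qualitative increase of hip/knee excursion with gravity; vertical GRF
peaks rise monotonically from roughly 0.6 BW at 0.17 g to 2.8 BW at 1 g.

What the generator does **not** emulate: marker-level noise and soft
tissue artefact, inverse-kinematics error structure, 3-D motion
(mediolateral forces, non-sagittal joints), hopping-frequency drift within
a trial, and harness force fluctuations (the support force is constant).
Passing tests therefore demonstrate the pipeline's internal consistency
and solvability under realistic magnitudes, not its accuracy on real
motion-capture data.

## Preprocessing

Touchdowns are vertical-GRF rising crossings of 10 N that stay above
threshold for 50 ms (the hold rejects sensor-noise crossings). Trials are
cropped to [first touchdown − 0.15 s, second touchdown + 0.15 s]; a
0.12 s guard band of extra samples on each side supports the filter and
the spline so their edge transients fall outside the analysis window.
All streams are filtered at 6 Hz with a second-order Butterworth filter
applied forward-backward (zero phase; the effective order doubles), then
resampled to the 51 mesh points with interpolating cubic B-splines whose
exact derivatives provide velocities and accelerations. Net joint
moments come from inverse dynamics with the total GRF applied at the
recorded centre of pressure (converted to a foot-fixed point per frame)
and the support force at the pelvis COM; the pelvis rows are reported
separately as experimental residuals.

## Tracking optimal control problem

State trajectories are third-order polynomials on 50 equal mesh intervals
with three Radau collocation points per interval (four points counting
the interval start). Because the skeletal and muscle dynamics are
formulated implicitly — accelerations, activation rates and tendon-force
rates are controls — every collocation equation is linear, and the two
interior collocation states of each interval are eliminated analytically,
leaving one reduced linear constraint block per interval. Controls live
on mesh points and interpolate linearly. All nonlinearity sits in path
constraints at the 51 mesh points: Hill equilibrium per muscle,
muscle-moment/inverse-dynamics consistency at hip/knee/ankle, trunk
torque/inverse-dynamics consistency at the lumbar joint, zero pelvis
residuals, per-sphere equality of the GRF controls with the contact-model
forces, and the linear activation-rate envelope
`−a/t_deact ≤ ȧ ≤ (1−a)/t_act` (t_act = 15 ms, t_deact = 60 ms) implied
by first-order excitation dynamics with excitation in [0, 1].

Tracked quantities and scales: coordinates (rotations scaled by 2°,
weight 1; translations by 0.02 m, weight 0.01 — deliberately lenient on
pelvis height), total GRF (scales [5.1, 50] N, weight 1) and
mass-normalised net joint moments (scale 28.6, weight 10). The moment
and force scales are derived as the loads performing 1 J of work over the
kinematic scales (the horizontal force scale is the vertical one reduced
by 9.81), rounded to 3 and 2 significant figures. Effort weights
activations squared by muscle volume percentage; control regularisation
scales each rate control by its bound and reserves by 2 N m. Integrals
use trapezoidal quadrature on the mesh grid.

Decision variables are scaled affinely to [−1, 1] by their bounds.
Coordinate and velocity bounds are the model ranges of motion intersected
with a window around the tracked trajectory (±0.30 rad / ±0.10 m on
positions); rate-control bounds (300 rad/s², 200 /s for tendon-force
rates, 70 /s for activation rates) double as the cost scales. Contact
stiffness/damping bounds are [1e5, 1e7] and [0.1, 4]; sphere positions
may move ±0.03 m fore-aft but only ±0.005 m vertically — the vertical
direction is nearly redundant with ground penetration and wider bounds
make the identification degenerate.

Two initial guesses are built. The data-informed guess copies the
experimental kinematics and seeds the GRF controls with the contact-model
forces along the experimental motion at the starting contact parameters
(stiffness 1e6, damping 2, spheres at their anatomical positions); muscle
states are seeded by a per-node static optimisation (volume-weighted
least-squares moment distribution with an active-set on the activation
box, followed by a static Hill solve for the tendon forces). The cold
guess sets every variable to zero, or to its nearer bound where the
bounds exclude zero. Both guesses share the stated contact-parameter
starting values. The enriched warm start is a solver-robustness choice:
with all muscle variables at their lower bounds the first feasibility
steps are large and throw the iterate into poor basins.

The nonlinear program is solved by an equality-driven sequential
Gauss-Newton method written for this problem: each iteration linearises
the path constraints (sparse Jacobian by sparsity-grouped finite
differences on the scaled variables), forms the Gauss-Newton Hessian of
the objective (exact for the quadratic terms, J^T W J for moment
tracking), and solves one sparse KKT system (SuperLU, MMD_ATA ordering)
for the step; globalisation is an l1-merit backtracking line search with second-order
corrections, a short nonmonotone (watchdog) reference, a feasibility-
restoration step when the search fails while infeasible, an infinity-norm
step cap of 0.25, a Levenberg parameter, and active-set handling of both
the box bounds and the activation-rate inequalities (the bound set
persists across iterations). The static contact parameters carry an
extra step regularisation (5.0) so they move quasi-statically, and the
contact-consistency rows are expressed in penetration-equivalent units
(scaled by 1/stiffness) so feasibility cannot be bought by softening the
contact. The
solver declares convergence when the scaled constraint violation falls
below 1e-6 (constraint rows are scaled to order one: 100 N m for moment
rows, 500/100 N for residual rows, 200 N for contact rows) and either
steps stagnate, the objective stagnates, or the merit function admits no
further decrease at a feasible point. Both guesses are attempted and the
lower-cost converged solution kept (ties favour the data-informed guess);
the cold guess is given a small iteration budget (20) since it
essentially never converges within a sensible time on this problem, and
the convergence criterion requires only one converged guess.

Problem sizes used in the shipped experiments: 50 mesh intervals, 3576
decision variables after condensation, 1750 reduced collocation rows,
1071 nonlinear path-constraint rows, 1020 linear activation rows. A warm
solve takes 40–250 iterations (roughly 1.5–3 s each on one CPU). The
acceptance experiment runs one trial per gravity level with a 140/20
iteration budget, a problem size chosen so the five solves complete in
about a quarter of an hour.

## Joint reaction forces and summaries

The reaction at a joint is computed from the free body of the segments
distal to it: inertial-minus-gravitational wrench of the distal segments,
minus external forces on them, minus the pull of every muscle crossing
the joint (applied along the path segment that crosses the joint, pulling
the distal side towards the proximal side). By default the force is
resolved in the child segment frame with the compressive (long-axis)
component positive; a `frame="lab"` switch reports the laboratory
vertical component instead. Peaks are signed extrema of largest
magnitude; impulses are trapezoidal integrals over the cycle,
body-weight-normalised (1 g body weight). Reserve acceptance follows the
5 N m / 10%-of-net-moment rule, with the fraction evaluated only where
the net moment exceeds 1 N m (the ratio is meaningless at moment zero
crossings).

## Adaptation model

The CSA growth equation is separable, so a closed-form solution exists
for any force profile; the numerical path (adaptive Runge-Kutta per
repetition) is retained as the public API and the closed form doubles as
its test oracle and as the exact inversion inside `reps_to_target`. The
drive is clamped at zero below the threshold `F₀ = 0.2` (growth-only, no
atrophy branch), repetitions are back-to-back repeats of one hopping
cycle's quadriceps profile (rest between repetitions is not modelled; the
calibrated rate constant absorbs it), and the quadriceps force is the
summed tendon force of rectus femoris and the three vasti normalised by
their summed maximum isometric force. `δ` and `τ` are degenerate up to a
product, so calibration fixes `δ = 1` and fits `τ` by root finding
against a reference schedule: a resistance-training programme in
untrained adults reaching the minimal worthwhile increase (+3.37%) after
about two weeks — taken as 216 repetitions at 70% of maximum load, 3 s of
loading per repetition — with `CSA_max = 1.4`. Set arithmetic is
week-normalised: sets per session = ceil(reps / 12 / 3). Absolute
repetition counts from these defaults are not comparable to
participant-specific values; comparisons between gravity conditions are
the intended use.

## Known limitations

* Planar, single-leg; no mediolateral mechanics, no subtalar/toe joints.
* The tracked moments use the muscle-side (muscle + reserve) moments;
  these equal the inverse-dynamics moments only to solver feasibility
  tolerance.
* Contact damping is weakly identifiable from filtered data; stiffness
  recovery is tested, damping is not.
* The SQP solver is tailored to warm, near-feasible starts; cold starts
  generally stall and are only attempted, not relied upon.
* The adaptation model inherits all caveats of a single-mechanism
  (tension-driven) hypertrophy description.
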