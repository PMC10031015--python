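# Methods

`gaitgrf` predicts ground reaction forces and moments (GRF&Ms) during
walking from full-body kinematics alone, by embedding a conditional
foot–ground contact model in a per-frame actuator-recruitment optimization,
and quantifies how those predictions propagate into clinically reported
joint moments. Because it ships no patient data, it also contains a
first-class synthetic-gait generator that produces typical and hemiplegic
(Rodda type 1–4) trials together with dynamically consistent "measured"
kinetics, so the whole chain can be validated against a known ground truth.

## Rigid-body model

Eight segments — pelvis, a lumped trunk (trunk + head + arms, rigidly
attached to the pelvis), and per leg a thigh, shank and rigid foot — form a
pelvis-rooted tree with a 6-DoF floating base, 3-DoF ball-and-socket hips
(intrinsic X–Y–Z Euler: ab/adduction, flexion, internal rotation) and 1-DoF
hinge knees and ankles (about the medio-lateral axis). An optional subtalar
hinge can be enabled and is off by default: the rigid foot is the minimal
choice consistent with the prediction method, and its limitations
(no mid-foot break, distal-edge pivot during heel rise) are inherited
deliberately.

Segments are scaled linearly from two anthropometric inputs, body mass `m`
and stature `H`, using a classical fraction table (Winter, *Biomechanics
and Motor Control of Human Movement*, Table 4.1): masses as fractions of
`m` (pelvis 0.142, thigh 0.100, shank 0.0465, foot 0.0145 per side; the
lumped trunk closes the sum to exactly 1), lengths as fractions of `H`
(thigh 0.245, shank 0.246, foot 0.152), COM positions and radii of gyration
as fractions of segment length, inertia scaling as `m L²`. The defaults for
the synthetic cohort are the grand means of the emulated hemiplegic
subgroups: `m = 41.8 kg`, `H = 1.47 m`. Foot width defaults to 0.40 of foot
length. Lab frame: X = walking direction, Y = medio-lateral (left
positive), Z = up; ground reactions are forces ON the body, vertical
positive up.

## GRF&M prediction

Under each foot, 25 contact nodes on a deterministic 5×5 grid span the sole
(−0.25 to +0.75 foot lengths fore–aft of the ankle, full sole width, at
floor level in the neutral pose). Each node carries five unilateral force
actuators with generators `(±μ, 0, 1)`, `(0, ±μ, 1)` and `(0, 0, 1)` —
a five-generator approximation of the Coulomb friction cone with `μ = 0.5`.
The strength available to every actuator of node `p` is conditioned on the
node's height and speed,

```
c_p = N_max · z_smooth(p_z / z_lim) · v_smooth(|p_vel| / v_lim)
```

where each factor equals 1 below its knee (0.8 for the height ratio, 0.15
for the velocity ratio), follows the half-cosine
`(1 + cos((ratio − knee)·π/(1 − knee)))/2` on `(knee, 1]`, and is 0 above
1. Defaults: `N_max = 0.4·m·g`, `z_lim = 0.03 m`, `v_lim = 0.8 m/s`. The
factorized form is continuous everywhere and coincides with the piecewise
definition on its unambiguous regions; node speed is the magnitude of the
full 3-D node velocity; heights below the floor are clamped to zero with a
warning.

Per frame, the required generalized forces `b` are obtained from
virtual-work (Newton–Euler) inverse dynamics with no externals; velocities
and accelerations come from central differences, with rotations differenced
on the rotation manifold. Actuators are then recruited by minimizing the
sum of squared activities `(f/strength)²`, subject to the generalized
equations of motion:

* contact actuators (unilateral, strengths `c_p`, mapped through the
  contact-point Jacobian transpose; actuators below `10⁻⁶` body weight are
  dropped),
* one bidirectional constant-strength torque actuator per joint DoF
  (default strength 3 N·m per kg body mass — an idealized stand-in for a
  muscle set that preserves the recruitment structure without muscle-path
  geometry),
* six weak residual actuators at the pelvis (force and moment, strengths
  1% body weight and 1% body weight × 1 m) that keep the problem feasible
  when the required wrench leaves the contact cone.

With the bidirectional variables eliminated (each is fully determined by
the contact forces through its own equation), each stage of the solve is
exactly a nonnegative least-squares problem, solved with a deterministic
active-set method (`scipy.optimize.nnls`). The residual actuators are
treated lexicographically rather than jointly: stage 1 finds the smallest
achievable residual activity — force components before moment components,
because a required force inside the friction cone is always achievable
during support whereas a required free moment may not be, and an
unachievable moment must not corrupt the predicted forces — and stage 2
minimizes contact-plus-joint effort subject to that residual (enforced by a
heavily weighted penalty, relative equality error below 10⁻⁶). A
consequence worth stating plainly: whenever only one foot can generate
contact force, the equations of motion pin that foot's predicted force
exactly, which is the single-support "direct solve" limit of the method.
During double support the load distribution is the recruitment optimum and
is deterministic for fixed inputs.

Per-foot wrenches are the sums of node forces and their moments about the
lab origin; the centre of pressure is reported where the predicted vertical
force exceeds 5 N. Predictions are raw; comparisons apply the same
zero-phase 2nd-order 12 Hz Butterworth filter to predicted and measured
signals.

## Synthetic gait and ground-truth kinetics

The generator prescribes the foot–ground interaction and derives joint
angles from it, because that is what the contact model is conditioned on:

* stance: the foot is anchored (flat contact for typical gait, forefoot
  contact for equinus presets) with a smooth sagittal pitch profile and a
  push-off heel rise pivoting about the distal sole edge;
* swing: horizontal travel and foot pitch settle early (quintic
  smoothsteps), the vertical path rises quickly after toe-off, clears, and
  descends late and gently onto the next foothold — so the node strengths
  of a landing foot ramp in gradually, as for a real landing;
* leg joint angles come from closed-form two-link geometry inside the
  hip-ab/adduction-tilted leg plane, with a smooth minimum-knee-flexion
  floor during swing (near full extension the two-link inverse geometry has
  unbounded curvature, which would inject acceleration spikes);
* the pelvis advances one stride per stride with small vertical (2
  cycles/stride), medio-lateral and yaw (trunk counter-rotation)
  oscillations; feet are placed 0.03·H from the midline (narrow-base gait).

A balance-refinement loop then reshapes the horizontal pelvis path so that
the motion's zero-moment point tracks the support schedule (heel-to-toe
progression under the stance foot; cubic-smoothstep transfer during double
support). Because the gait is stride-periodic, the ZMP-to-pelvis inversion
is solved per Fourier harmonic (quasi-static transfer
`m_eff (g + z̄ω²)/F̄z`, harmonics above 20 Hz untouched, under-relaxation
0.5, computations on a one-stride-padded grid so differentiation endpoints
never contaminate the estimate). This is what makes the synthetic trials
dynamically balanced: the wrench they require stays within what foot–ground
contact can physically supply.

Pattern presets impose their defining signatures only: equinus presets use
forefoot contact with a plantarflexed pitch profile plus a smooth
plantarflexion floor on the affected ankle coordinate (a contracture model;
on the rigid sole the toe may dip ~1 cm below the floor in late stance — a
known artifact that affects neither dynamic consistency nor the contact
solver, which clamps node heights at the floor); the drop-foot preset adds
a mid-swing plantarflexion bump; recurvatum mirrors the knee branch of the
two-link solution over a mid-stance window (the hip–ankle chord is even in
the knee angle, so the anchored foot is preserved); jump-knee presets lower
the pelvis; equinus presets vault (a localized pelvis lift over the
affected stance) and place the sound foot on a mildly raised forefoot —
both documented clinical compensations of toe-walkers. Defaults: 150 Hz,
cadence 112.5 steps/min (an integer number of frames per stride, so
periodicity is testable at machine precision), double-support fraction
0.10, stride 0.70 m (typical) / 0.50–0.55 m (pathological presets).

Ground-truth kinetics are constructed from the same trajectory: the total
required wrench (Newton–Euler aggregation) is assigned entirely to the
stance foot in single support and split by a cubic smoothstep across each
double-support window; per-foot CoPs follow a linear heel-to-toe
progression and are least-squares adjusted (minimal-norm CoP shifts plus
free vertical moments) so the per-foot wrenches sum *exactly* to the total
at every frame. A foot counts as in contact when its lowest sole corner is
below `z_lim = 0.03 m` — the same height at which contact nodes can first
generate force, so "single support" in the ground truth coincides with
"only one foot can push" in the predictor. Band-limited (≤ 10 Hz) joint
noise and isotropic marker noise are available and default to zero; marker
noise amplitude is parameterized as the mean 3-D perturbation distance (the
same scale as the reported mean marker tracking error), i.e. per-axis
σ = amplitude·√(π/8).

What the generator does *not* emulate: arm swing and articulated-trunk
compensation, soft-tissue artifact structure, trial-to-trial motor
variability, mid-foot break, spasticity dynamics. Passing tests therefore
demonstrate internal consistency of the method under idealized, dynamically
balanced kinematics — not clinical accuracy on real recordings, where
marker error and model mismatch propagate into the predictions.

## Joint moments and statistics

Hip, knee and ankle intersegmental moments are Newton–Euler sums over the
distal subtree about the joint centre, projected onto the proximal
segment's axes (a simplification of non-orthogonal clinical axis
conventions, applied identically to measured- and predicted-based
computations so their differences are unaffected), signed so extensor /
plantarflexor / abductor moments are positive, and normalized to body mass.

Comparisons run per gait cycle: events at 20 N vertical-force crossings
(50 ms minimum inter-event gap against chatter), time normalization to 101
samples from foot-strike to foot-strike, RMSD (absolute and as % of the
measured curve's maximum magnitude), Pearson correlation with the
conventional bands (weak ≤ 0.35 < moderate ≤ 0.67 < strong ≤ 0.90 <
excellent; boundaries belong to the lower band), and normalized circular
cross-correlation over ±25% of the cycle (ties to the smallest lag).
Representative-trial selection returns the trial whose curves are closest
(mean RMSD over planes) to the across-trial mean, ties to the lowest index.

The 1-D statistical parametric mapping uses the nonparametric sign-flip
permutation variant: pointwise paired t statistics over the 101 nodes, a
family-wise threshold from the permutation distribution of the curve
maximum of |t| (all 2ⁿ sign flips when 2ⁿ ≤ n_perm, otherwise seeded random
flips including the identity), supra-threshold clusters reported with
max-statistic permutation p-values. Random-field-theory thresholds are out
of scope. The implementation is validated by a null-calibration simulation
(family-wise error within the exact binomial 95% interval of α = 0.05 over
1000 replicates) and a power check (a 3-SD offset over 30–50% of the cycle
detected in ≥ 95% of replicates).

## Numerical choices and degenerate inputs

* Differentiation: central differences, one-sided at trial endpoints;
  endpoint frames are excluded from kinetic assertions. Rotations are
  differenced via the relative-rotation logarithm.
* The recruitment solve is deterministic (active-set NNLS, fixed
  iteration caps); solver failures flag the frame and the pipeline
  continues.
* Equality enforcement weight 10⁶ per scaled row; contact actuators with
  strength below 10⁻⁶ body weight are dropped to avoid ill-conditioned
  activities.
* Zero-variance curves, zero reference maxima, sub-threshold force series
  and missing marker segments are flagged (warnings or per-frame flags),
  never silently filled.
* Text formats (TRC, MOT/STO) are written with 17 significant digits and
  round-trip losslessly; unknown configuration keys and unit tags are
  rejected.

## Known limitations

* The generator's double-support load split (smoothstep) is a convention,
  not a measurement; the recruitment optimum differs from it in detail, and
  those differences dominate the residual disagreement between predicted
  and ground-truth curves.
* Free vertical moments demanded by the (armless, rigid-trunk) model
  occasionally exceed what the friction generators can supply; the
  lexicographic residual treatment confines the effect to the moments.
* The rigid foot cannot represent mid-foot break; equinus presets pivot on
  the distal sole edge instead of anatomical metatarsal heads.
* Scaling fractions come from adult cadaver data applied to child-sized
  models — the same pragmatic mismatch the method faces in practice.
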