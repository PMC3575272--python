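# Methods

This note documents the model equations, the numerical choices, the
synthetic study conditions, and the limits of what the tests demonstrate.

## Plant

Two rigid links — legs (both legs lumped, knees locked) and torso
(head-arms-trunk lumped) — connected to a translating platform at a
2-DOF ankle (pitch + roll) and to each other at a 2-DOF hip; axial yaw
is locked at both joints, so the state is the four joint angles and
their rates.  Angle conventions: x forward, y rightward, z up; pitch
positive forward, roll positive rightward; link orientation is pitch
followed by roll.  Applied joint torques are the generalized forces
conjugate to the joint angles (a positive sagittal torque accelerates
the joint forward).  There is no passive joint stiffness or damping, no
foot geometry, and no ground-contact model: the platform prescribes the
ankle point's horizontal acceleration.

The equations of motion are derived once per session, symbolically,
from the Lagrangian written in a frame translating with the platform;
base excitation enters as the horizontal pseudo-force −m·a at each mass
center.  The derivation is lambdified and jit-compiled (the compiled
functions are bit-identical to the interpreted ones).  An independent
re-derivation with Kane's method (different algorithm, different code
path) agrees with the plant to ~1e-13 relative on random states; the
passive plant conserves energy to ~2e-7 relative over 5 s at the 1-ms
default step, and the analytic linearization about upright matches
finite differences to better than 1e-6.

Anthropometry: link masses and lengths are fixed fractions of subject
mass and height from a standard segment-parameter table (legs =
2×(thigh+shank), feet excluded since the model has no feet; torso =
head+arms+trunk).  Inertias come from closed-form solids — a cylinder
for the legs, an ellipsoid for the torso — with dimensions fixed
fractions of link length.  The shipped table is a documented stand-in,
fully overridable via the `anthropometry` config section; the default
subject (1.78 m, 86 kg) gives legs 25.2 kg / 0.874 m and torso
58.3 kg / 0.837 m.

## Center of pressure

The COP is computed from the ground-reaction wrench at the ankle: force
= total inertial force minus weight, moment about the ankle = sum of
each link's rotational term (Iω̇ + ω×Iω) plus r×ma minus the gravity
moment; the COP is the surface point where the reaction's horizontal
moment components vanish (x = −M_y/F_z, y = M_x/F_z).  This standard
reaction-wrench definition is a reconstruction — the reference modelling
work does not state its COP computation.  Under a static lean the COP
equals the COM projection exactly, and the implied holding torque obeys
|COP| = T/(m g).  A non-positive vertical reaction raises a
model-validity error (the model has no airborne regime).

## Controller and the delay margin

Each plane has an independent static delayed full-state feedback
T = −K x(t−t_d); no estimator, predictor, noise, or sensory-integration
stage.  The delay is rounded to whole integration steps and realised
with a ring buffer.

The default delay is **0.05 s**, not the ~0.1 s often quoted for
long-latency postural responses, and this is a measured constraint, not
a convenience: on the exact delayed sampled-data loop, the minimum
stabilizing ankle stiffness is gravity-bound (~820 N·m/rad, and LQR
solutions saturate near 1.2× that in the expensive-control limit) while
the plant's fast unstable coupled mode sits at 9.4 rad/s, which caps
the stabilizable delay for *any* static gain near 0.07 s.  Real stance
tolerates longer latencies through prediction, which this model class
deliberately omits.  Configurations are free to set `t_d_s` anywhere
the loop remains stable.

Demonstration gains: sagittal from a mildly weighted LQR
(Q = diag(50, 10, 10, 2), R = diag(0.05, 0.1)); coronal from a frozen
matrix obtained by minimizing the delayed-loop ML impulse-response
energy at fixed spectral-radius margin (LQR weights cannot make the
coronal plane meaningfully stiffer here, see above).  The result gives
peak ankle torques of ~105 N·m and peak sway of ~1.3° for a 60-mm
backward perturbation, and an ML response about half the AP amplitude
under oblique perturbations — qualitatively emulating the higher
effective ML stiffness of stance.  These are demonstration values, not
fitted reproductions of any experiment.

## Biofeedback device and torque

The device senses the torso inclination components (small-angle: AP =
ankle+hip pitch, ML = ankle+hip roll), forms the feedback magnitude
m = inclination + ½·(inclination rate) (deg, deg/s), and compares m —
not the raw inclination — against the 1° dead zone and the row
thresholds (defaults 1°, 2°, 3°; the experimental row coding beyond the
dead zone is not published, so the thresholds are a documented
reconstruction).  The column nearest the tilt azimuth is displayed
(ties go to the lower azimuth, deterministically).  The torque target
decomposes along the *displayed* column azimuth — the only reading
under which display resolution can affect the model at all — and the
torque state relaxes toward it through the first-order lag, integrated
by its exact exponential within each step so the display switching
never creates torque discontinuities.  The applied generalized torque
carries a restoring sign: a displayed forward-tilt cue with positive k
opposes forward tilt.  Cosines/sines of column azimuths are evaluated
exactly at multiples of 90°, which keeps cardinal-direction runs
bit-exactly planar.

## Closed-loop integration

One fixed-step grid (default dt = 1 ms) is shared by plant, delay
buffer and lag.  Device logic runs once per sample and is held over the
step; the continuous parts are evaluated at the RK4 stage times — the
delayed state by cubic-Hermite interpolation in the history buffer
(method-of-steps dense output, end-of-step derivative seeded with the
final RK stage), the lag by its exact exponential, and the platform
acceleration analytically with left-limits at phase boundaries (the
trapezoid's acceleration jumps are grid-aligned; boundary comparisons
snap within 1e-9 s to absorb float drift).  Halving dt from the default
changes the windowed sway by ~1e-6 deg RMS.  Falls (any joint angle
beyond ±π/2) abort with a diagnostic; the study regime stays far from
that threshold.

Trajectories record sway (torso inclination components, deg), COP (cm),
all torque channels split into controller and biofeedback parts,
platform motion and tactor activation, and are written as full-precision
CSV (write→read is bit-exact).

## Metrics

Average error = mean absolute instantaneous difference, and
cross-correlation = zero-lag normalized coefficient
Σ(e·s)/√(Σe²Σs²), both over a 3.00-s window from perturbation onset
(onset sample included) on the 100-Hz grid.  No mean subtraction (zero
is meaningful — upright) and no lag search by default; a max-over-lags
variant exists behind a flag.  The published validation table ships as
a CSV resource; its four 15-cell block means are recomputed, not
hard-coded, by `table1_summary`.

## Fitting

The objective is the time integral of the **square of the sum** of the
included channels' normalized residuals (normalization by the peak
reference magnitude per channel), matching the printed form of the
original objective including its cross-terms; a conventional
sum-of-squares switch exists (`sum_form="sum-of-squares"`).  Excluded
per direction: AP sway at 90°, ML sway at 180° (the plant's response is
exactly unidirectional there, so those reference channels carry no
signal and their normalization would vanish), plus any channel with
zero reference peak.  The fit window equals the metrics window; failed
simulations return a large penalty rather than raising.

Stages: (1) optional one-at-a-time sensitivity screen to shrink the
sweep space for coupled (oblique-direction) fits; (2) exhaustive
parameter sweep on a grid, ties resolved first-come; (3) Perpendicular
Search — the term is not defined in the source literature, so the
package provides the standard reading (cyclic coordinate descent with
±probes, per-axis acceleration, Hooke-Jeeves-style pattern moves and
step halving) and a rotating-orthogonal-directions variant
(Rosenbrock's scheme) for curved valleys; (4) a Gauss-Newton polish
(Levenberg-Marquardt on the stacked residual vector with a
finite-difference Jacobian, ~1 extra simulation per parameter per
iteration).  The polish is what makes exact recovery practical: the
objective has a strongly correlated gain valley (conditioning ~1e4)
along which all direction-set schemes tested — both package variants
and an external Powell implementation — stall around J ≈ 6e-6, whereas
the damped Gauss-Newton sequence reaches the valley floor (J ≈ 1e-31 on
noiseless references) in under ten residual evaluations.  The k-row
ordering constraint k₁ ≤ k₂ ≤ k₃ is enforced by projecting every probe
into the interval spanned by its row neighbours.

### Identifiability

The gain valley has a physical meaning: several gain combinations
produce nearly identical closed-loop trajectories, so reference noise
is amplified into parameter error along that combination by a measured
factor of ~32% relative gain error per 0.01° of sway-channel noise.
Noiseless synthetic references therefore recover all 8 sagittal gains
to machine precision, and biofeedback parameters (τ_F and the nonzero k
components) likewise; references at the default fixture noise (0.002°
sway / 0.008 cm COP, the level chosen so that across-subject-averaged,
low-pass-smooth trajectories are emulated and the documented 10%
recovery property holds with margin) recover gains to ~8%; noise at
0.02° — still far below raw single-trial variability — already degrades
the weak combination to ~50%.  Fitted gain values from this model class
should accordingly be read as trajectory-equivalent representatives,
not as uniquely identified physiological constants.

## Synthetic study conditions

The default fixtures reproduce the study conditions: subject 1.78 m /
86 kg (study means), perturbation travel 60 mm (midpoint of the printed
50–70 mm range) with 100/200/100-ms phases, directions 90°/180°/225°,
0.5-s settling margin before onset, 100-Hz output.  Biofeedback
defaults mirror the qualitative fitted-model features reported for this
device class — coronal k-vectors zero, no hip torque from the first
tactor row, ankle biofeedback torques of a few N·m — and τ_F = 0.25 s
as a plausible volitional reaction constant; none of these are printed
fitted values.  Fixture noise is smooth (2nd-order Butterworth-filtered
Gaussian, 5-Hz cutoff) because averaged trajectories are smooth; white
noise would distort the fit disproportionately.

What passing tests do **not** show about real data: the references are
generated by the same model family that is being fitted, so recovery
tests demonstrate the correctness and conditioning of the pipeline, not
the adequacy of the two-link model for human responses; and the
demonstration gains/torque scales are illustrative, so metric values
against synthetic references say nothing about fit quality to actual
averaged subject trajectories (which are not publicly deposited).

## Display-resolution degeneracy

Whenever the displayed column sequence of two display configurations
coincides, the biofeedback torques — and hence the trajectories — are
identical, because the display enters the model only through the
displayed azimuth and row.  For 90° and 180° perturbations the tilt
azimuth stays exactly on a column shared by the 4- and 16-column
displays, so their responses are identical by construction (the
experimental protocol made the same observation).  For 225°
perturbations the model's tilt azimuth passes near 45° — a column the
4-column display lacks — at some display-active samples, so full
coincidence is not guaranteed with a physically near-symmetric plant;
the degeneracy then holds in prefix form (trajectories bit-identical up
to the first column mismatch), and the mechanism, not an accidental
cancellation, is what the tests assert.

## Known limitations

Small-perturbation regime only (no nonlinear postural strategies, no
stepping, no arm motion); deterministic (no motor or sensor noise, no
trial-to-trial variability); no cognitive-load effects; no gait; the
delay ceiling discussed above; COP is not saturated at a base of
support; and the anthropometric fraction table is a stand-in rather
than the original study's source tables.
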