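# Methods

`pursuitdcm` implements a dual dynamic-causal-modelling pipeline: a
behavioural DCM that estimates subjective precisions from smooth-pursuit
eye trajectories, and an electromagnetic DCM that estimates
condition-specific synaptic gain changes from evoked sensor responses,
linked by a cross-subject correlation between the two precision
estimates. Because no recorded eye-tracking or MEG data ship with the
package, every stage is validated against synthetic cohorts with known
ground truth.

## The pursuit model

A target moves sinusoidally along a horizontal path (period 3.94 s,
normalized half-extent 1; the recorded geometry — 37.0° path — is kept
as metadata only). The path segment between the midline and the
furthest 10% from the start is occluded (40% of the path). In the Noisy
condition a stochastic perturbation is added to the target's phase.

The *generative process* (world) provides two sensory modalities: the
proprioceptive gaze angle, and a bank of 17 Gaussian receptive fields
reporting the retinotopic angle between gaze and target, silenced while
the target is occluded. The eye is a first-order plant whose velocity
relaxes toward the action variable.

The *generative model* (agent) believes gaze `x_o` and target `x_t` are
drawn to a fictive attracting location `v` that moves sinusoidally with
a phase *lead* over the target:

    dx_o  = x_o'
    dx_o' = kappa_v (v - x_o) + kappa_t (x_t - x_o) - theta2 x_o'
    dx_t  = x_t'
    dx_t' = 1/4 (v - x_t) - theta6 x_t'
    v     = exp(theta7) cos(2 pi t + exp(theta8)) + omega_v

Each attraction weight has a fixed and an occluder-dependent component:
`kappa_v = theta1 + occluded * theta4`,
`kappa_t = theta3 + (1 - occluded) * theta5`, so occlusion strengthens
the pull of the hidden location and weakens the pull of the target —
this is what produces anticipatory movements. The agent's occluder is
sigmoid-softened (width 0.02) to keep gradients defined.

### Time units and parameter defaults

The kinetic equations are written per *characteristic oculomotor time
unit*; one stimulus cycle spans 32 such units (~123 ms per unit at the
3.94 s period), which makes the printed O(1) kinetic constants a
well-conditioned tracker of the unit-frequency attractor and makes the
natural phase-lead unit 2π/32. Defaults:

| parameter | value | meaning |
|---|---|---|
| theta1 / theta4 | 0.25 / 1.5 | gaze→attractor pull, fixed / under occlusion |
| theta3 / theta5 | 0.5 / 1.5 | gaze→target pull, fixed / when visible |
| theta2 / theta6 | 0.5 / 0.25 | viscosity of gaze / target motion |
| theta7 | 0 | log amplitude of the attractor |
| theta8 | ln(2π/12) | log phase-lead of the attractor |
| ln Π_s, ln Π_x, ln Π_v | 4 | log-precisions (sensory, state motion, cause) |
| prior variance | 1/2 | for every estimated log-scaling/offset |

The printed source for the kinetic and prior cells is typographically
corrupted; only the log-precision prior (4) and the prior variance
(1/2) are treated as authoritative. The remaining values are package
defaults chosen once so that (i) the closed loop tracks the stimulus,
and (ii) occlusion boosts attraction to the hidden location, and are
echoed into every output. The phase-lead default (2π/12 rather than
the 2π/32 natural unit) gives the attractor roughly one occluder-
crossing of lead; it is what makes the precision phenotype (below)
large enough to estimate.

## Generalized filtering and action

Beliefs are represented in generalized coordinates (value, velocity,
acceleration, ...): embedding order 4 for hidden states, 2 for causes
and sensory data. Analytic fluctuations carry a Gaussian
autocorrelation of scale 1/2 time unit; its induced covariance over
derivative orders defines the generalized precisions
(`generalized_precision`). Free energy is the precision-weighted sum of
squared sensory, state-motion and cause prediction errors; the
mean-field complexity terms are omitted from the *simulator's* descent
(they are retained in the inversion engine, where they define the
evidence).

Perception integrates `mu_dot = D mu - dF/dmu` with a backward-Euler
step on the Gauss-Newton linearisation, which keeps the stiff
precision-weighted flow stable at 1–5 ms resolution. Action descends
free energy through the order-1 proprioceptive prediction error only
(`a_dot = -lr_a * [Pi_s eps_s]_prop'`, identity inverse model), with
`lr_a = 8` per time unit. Sensory precision is balanced per modality:
the single proprioceptive channel carries the same total weight as the
17 retinal channels together, and retinal data enter at order 0 only.
Without this balance the retinal population outvotes proprioception,
the gaze belief absorbs retinal slip, and the action loop runs away —
a credit-assignment failure, not a numerical one.

Correctness of the filter is anchored by a linear-Gaussian reduction:
on a noiseless damped oscillator the generalized filter's steady state
matches a Kalman filter to well under 2% RMS.

## The precision phenotype

Simulating pursuit across ln Π_s levels between the Smooth (4.0) and
Noisy (5.57) condition values produces two monotone effects: the eye's
phase lag behind the target (projection of the settled eye trace on the
stimulus fundamental) increases, and the peak anticipatory displacement
during occlusion decreases. Mechanism: precise sensory input anchors
the beliefs to the (trailing) data and suppresses the anticipatory pull
of the leading attractor. Below ln Π_s ≈ 3.8 the loop becomes erratic
(weak data anchoring), above ≈ 6.3 the Noisy condition approaches
instability; the cohort generator therefore truncates subject effects
to keep every subject in the validated operating band.

## The Noisy condition

Taken literally, per-millisecond phase-walk increments of variance
exp(−0.5) diffuse the phase by tens of radians within a cycle: the
instantaneous target becomes white noise and its ensemble-average path
flat — an untrackable stimulus. The stimulus module implements the
literal walk (and the calibration check measures exactly that per-ms
increment variance), but the closed-loop simulator's Noisy condition
defaults to a bounded, mean-reverting phase jitter (OU process,
stationary SD 0.8 rad, 10 ms correlation): fluctuations far too fast to
track, around an average path that remains the underlying sinusoid.
The behavioural data feature is accordingly defined against the
*expected* target path (the hidden sinusoidal cause), not the jittered
sample path.

## Behavioural inversion (meta-Bayesian)

The data feature is the cycle-averaged, unit-amplitude-normalized
position error a(t) = eye − expected target. Its generative model is
the pursuit simulator itself: p(a | params) = N(a*, Σ) with a* the
simulated position error and i.i.d. Gaussian observation noise whose
log-precision is estimated (an AR(1) pre-whitening option exists).
Inversion is by variational Laplace (below) over additive offsets from
the prior expectations, prior variance 1/2.

Two practical points. First, the waveform's mean-square distance to
data is *multimodal* in the ln Π_s offset (waveforms at offsets ~−0.2
and ~+1.4 resemble each other), so fits are initialised from a dense
grid of candidate offsets. Second, for one-parameter precision fits
the prediction family is subject-independent, so it is tabulated once
on an offset grid (`PrecisionSurface`; the Noisy family as a frozen
12-seed ensemble mean over stimulus realizations) and served by
interpolation — inverting a subject then costs milliseconds. Data and
predictions always use the same integration settings, so
discretisation bias cancels.

## Variational Laplace engine

Gauss–Newton ascent on the Laplace free energy with a
Levenberg–Marquardt safeguard: accepted iterations never decrease F;
the observation-noise log-precision is conditionally maximised by
clipped Newton steps each iteration; singular curvature is
ridge-regularised. In the conjugate (linear-Gaussian, known-noise)
limit the posterior equals the closed form and F equals the exact log
evidence — machine-precision agreement is a test invariant. Jacobians
are finite-difference (forward differences in simulation-backed fits,
reusing the base prediction). Model averaging weights posteriors by
softmax(F) and moment-matches the mixture.

## Canonical microcircuit network

Each source has four populations (spiny stellate, superficial
pyramidal, inhibitory interneuron, deep pyramidal) with convolution
synaptic kinetics (two states per population; time constants 2, 2, 16,
28 ms; centered sigmoid firing). Forward extrinsic connections arise
from superficial pyramidal cells and drive spiny stellate (and weakly
deep pyramidal) targets; backward connections arise from deep pyramidal
cells onto superficial pyramidal cells and interneurons; lateral
connections (between homologous areas at every level, including central
V1 ↔ cuneus) act as both. All extrinsic connections are excitatory;
self-connections are inhibitory. The superficial-pyramidal inhibitory
self-connection is scaled by `exp(self_inhibition)`: larger values
reduce the population's gain; its impulse-response peak is strictly
decreasing in the parameter — the proposed synaptic encoding of
(inverse) precision.

The seven-source network (central V1, bilateral cuneus, V2, V5)
receives a gamma-shaped input burst (peak 16 ms) at its three sensory
sources. Extrinsic weights (forward 4, backward 0.5, lateral 0.5) are
set so responses remain comparable in amplitude across the hierarchy —
otherwise V5 is effectively silent and higher-level hypotheses are
untestable. A seeded random-orthogonal lead field (64 channels) stands
in for head modelling, with population weights 0.2 / 0.8 / 0 / 0.2
(interneurons unseen). Responses are integrated at 0.5 ms and fitted
over 0–200 ms after reduction to 8 spatial modes (computed from the
data covariance; with a synthetic lead field this is the faithful
stand-in for the forward-model-based construction).

Condition effects are log-scalings (B-effects) on self-inhibition and
forward connection strengths, prior N(0, 1/16). The hypothesis space
is the 2×2×2×2 factorial over {self-inhibition, forward} × {lower
(V1/V2), higher (V5)}; models are identified by their factor tuple (the
lexicographic numbering is recorded but carries no meaning).

## Preprocessing

Saccade masking (±35°/s criterion), per-cycle RMSE quality control
(flagging only — discarding is the caller's decision; the recording
geometry's 5.6 cm criterion is retained as metadata), cycle averaging
with unit-amplitude normalization, epoch mean- and baseline-correction
(−300..0 ms) and condition averaging. The pursuit artefact is removed
by regressing each channel of the averaged ERF on eye position and
projecting the resulting (standardised-coefficient) topography out of
every trial — a rank-1 signal-space projection, idempotent by
construction. Subject screening normalises per-subject mean
topographies to unit sum of squares, mean-corrects, takes the SVD and
flags subjects deviating > 2.5 robust SD on either of the two leading
projection axes (an aberrant minority topography can dominate either
component, depending on its size relative to ordinary between-subject
variability).

## Synthetic cohorts and the bridge

A cohort draws per-subject (Δln Π_s, ΔV1 self-inhibition) from a
bivariate Gaussian with correlation ρ (default −0.6, n = 17); the three
V1-group sources share the subject's gain change plus small per-source
deviations; V2 self-inhibition and lower forward B-effects are
independent nuisance draws. The group behavioural effect (mean 1.35
log-units, SD 0.3, truncated to [0.95, 1.75]; base offsets ±0.1) is
placed so every subject's Noisy-condition ln Π_s stays inside the
band where the closed loop is stable and the estimator's mapping is
steep and monotone (~[4.85, 5.85]); the induced attenuation of ρ is
modest and the generator records the truncated values as ground
truth. Defaults reproduce
the session structure: 10 blocks × 8 trials, 4 per condition per
block, 3 cycles per trial (40 trials / 120 cycles per condition),
1 kHz sampling; scaled-down runs (fewer, shorter, coarser trials) are
explicit constructions and are noted wherever used. Sensor data are
generated at SNR 5 (RMS signal / RMS noise).

Recovery: per subject, two single-condition precision fits give
Δ̂ln Π_s = Noisy − Smooth posterior offsets; inverting the generative
(lower-level) modulation model on the subject's condition ERFs gives
B̂ per connection, and "mean V1 self-inhibition" is the arithmetic mean
over central V1 and both cunei. The cross-subject Pearson correlation
between the two recovered quantities (with its exact t-based p, a
Bonferroni rule for the V1/V2 test family, and an OLS confound model
adding the position-error change as a regressor, df = n − 3) is the
pipeline's final output.

## Problem sizes and runtimes

The validation studies run at reduced sizes chosen as the package's
own defaults for desk-scale reproduction: behavioural fits at 5 ms
resolution on 2-cycle trials with 64 samples per cycle; sign-recovery
over 50 replicates with 2 trials per condition; model recovery over 20
noise replicates of the grand-average ERF; cohort bridge over 5
replicate cohorts with 8–10 trials per condition. Full-size runs only
change these counts.

## Known limitations

- The behavioural estimator's likelihood is multimodal in ln Π_s and
  the closed loop is chaotic-sensitive at mid precisions under phase
  jitter; occasional basin misassignments survive at scaled-down trial
  counts (they average out at the full 40-trial design).
- The simulator does not model saccade generation as a distinct
  mechanism, sensorimotor delays, 2-D gaze, binocular geometry, screen
  luminance, or realistic MEG noise spectra and head movement; passing
  tests show that the *pipeline* recovers what the generator planted,
  not that the model fits real recordings.
- The CMC rate constants and intrinsic gains are plausible defaults,
  not fitted quantities; the lead field is synthetic; source
  localisation is out of scope (source labels carry their MNI prior
  coordinates as metadata only).
- Backward-connection modulations are not part of the hypothesis space
  (responses are fitted only to 200 ms).
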