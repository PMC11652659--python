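# Methods

This note documents the models, conventions and numerical choices behind
`raffmap`, in the order of the processing chain.

## RAFF2 pulse synthesis

The pulse is defined by the rectified-sine AM / cosine FM pair with peak
amplitude `omega_1max = 2*pi*f1max` and initial phase `phi_0` (default 0;
the value used on scanners is not standardized, so it is configurable).
The FM function is converted to the phase modulation by running
integration (composite Simpson); against the closed form
`phi(t) = sin(omega_1max t + phi_0) - sin(phi_0)` the numerical phase is
accurate to better than 1e-9 rad at 1024 samples.

**Duration convention.** The default single-pulse duration is
`sqrt(2)/f1max`, the time over which the stationary doubly-rotating-frame
field (magnitude `sqrt(2)*f1max`) precesses the magnetization through two
full revolutions (4*pi rad).  This is the unique convention that ties the
625 Hz protocol frequency to the 2.26 ms printed pulse duration and it
makes `e_field_mag * duration * 2*pi = 4*pi` an exact identity, which the
test suite and the acceptance script verify from the synthesized waveform.

**Train arithmetic.** A preparation train of `n` pulses has
`n-1` spoiler gaps strictly between pulses; its total duration
`n*Tp + (n-1)*Ts` is the abscissa of the signal model.  With 2.26 ms
pulses and 0.7 ms spoilers this reproduces the protocol totals
22.98/46.66/70.34 ms for 8/16/24 pulses exactly.

**Transmit miscalibration.** The B1 scaling `eta_1` multiplies the AM
function only: a transmit-gain error scales the realized RF amplitude but
not the digitally synthesized phase ramp.

**Field trajectory.** The tilt angle of the first-rotating-frame effective
field is made continuous by carrying the sweep direction through the
`|sin|` rectification (the sign of the un-rectified sine, stored with the
waveform; a local-minimum heuristic covers externally supplied waveforms).
On resonance `|B_eff|` is constant to machine precision and the
second-frame field is `sqrt(2)*f1max` to better than 1e-6 relative on a
1e4-sample grid.

**RF power.** `rf_power_fraction` returns the time average of
`(omega_1/omega_1max)^2`.  For the sine AM over an integer number of
half-periods this is exactly 0.5 (half the power of a constant-amplitude
train of equal peak amplitude).  The default `sqrt(2)/f1max` duration
spans 2.83 half-periods, where the average is 0.525; both values are
pinned in the tests.

**Self-refocusing element.** `make_raff2_composite` builds the element as
P followed by P^-1 — the second half is the time-reversed,
phase-inverted (RF phase + pi, sweep negated) copy of the first.  On
resonance the second half exactly undoes the coherent rotation of the
first *for any transmit scale*, so across a spoiled train only relaxation
accumulates.  A static B0 offset cannot be negated and breaks the
cancellation, which is the mechanistic origin of the off-resonance
sensitivity of the maps.  The simulation layer uses this composite by
default (`pulse_scheme="pp_inv"`); the plain rectified-sine element
(`"plain"`) is retained for waveform-level analysis.  Without the
refocusing structure a spoiled train loses most of its magnetization to
the ~149 degree residual tilt left by each plain element, which both
collapses the signal and inverts the B1 trend relative to the physics the
composite reproduces.

## Bloch simulation

The integrator is piecewise-constant rotation stepping over the waveform
samples (hard-pulse approximation) with an exact relaxation sub-step after
each rotation.  Rotations are exactly norm-preserving; a guard refuses
steps rotating more than 0.1 rad (the waveform is linearly refined to
`dt_max`, default 10 us, before stepping).  The propagator reproduces the
closed forms it must: continuous-wave spin-lock decay `exp(-t/T2)` of the
locked component to 1e-6 and free T1 recovery to 1e-9.

Three series-simulation modes:

* **bloch** — plain T1/T2 relaxation during RF.  No exchange, dipolar or
  magnetization-transfer physics is modeled, so absolute fitted times are
  *not* tissue TRAFF2 values; the mode exists for physics sanity checks
  and for inhomogeneity *trends*, which are governed by field geometry.
* **phenomenological** — the preparation block multiplies Mz by
  `exp(-Tp/TRAFF2_true)` with `Tp` the *total* block duration including
  spoiler gaps, matching the abscissa convention of the fit.  (The
  per-step variant — decay of the component along the instantaneous
  effective field — is available in `propagate_pulse` for single-pulse
  studies.)  This mode provides exact ground truth for end-to-end fitting
  validation.
* **forward_model** — signals evaluated directly from the three-parameter
  model; no propagation.

**Readout.** The default "ideal" readout maps longitudinal magnetization
to signal as `S = sin(FA) * ((1-b)*Mz + b*M0)` with `b` (default 0.2) the
steady-state fraction sustained by the imaging pulses when the prepared
magnetization is destroyed.  This single mapping makes the no-prep,
prepared and saturation images internally consistent and is what gives the
model offset B its meaning; with `m0*sin(FA) = 1` it reproduces the
canonical A = 0.8, B = 0.2 example.  An optional bSSFP readout propagates
a linearly-ordered alternating-flip train (70 degrees, TR 3 ms, 73
segments) and samples the central k-space line, which under 6/8 partial
Fourier is segment 24.  Readout fidelity is deliberately not on the
validation path: A and B absorb readout effects by construction.
Rest periods (default 4 s) enter through T1 recovery only; cardiac
triggering is not simulated (voxels are static).

**Sequence order.** no-prep, trains in ascending duration, saturation —
with a rest period before every prepared acquisition.  Saturation is a
single parametric efficiency (default 1.0 = ideal); the multi-pulse
internals of WET-style saturation are out of scope.

## Phantoms and noise

The vial phantom places up to nine discs on a 3x3 grid.  Default T1
(297.8-1421.6 ms) and T2 (40.1-194.4 ms) spans match a commercial
relaxometry calibration phantom; the per-vial TRAFF2 ground truths
(101.7-550.8 ms, linearly spaced) are synthetic fixtures spanning the
range such phantoms exhibit — gel-vial TRAFF2 is governed by exchange
properties that T1/T2 do not determine, so no per-vial claim is made.
The short-axis phantom is an annulus (default myocardial TRAFF2 79.1 ms,
a typical healthy in-vivo value at 3 T) with blood pool, an anterior RV
insertion landmark, and an optional wedge lesion (default 87.4 ms against
a configurable remote value, an infarct-like contrast).  B0 maps default
to a smooth ramp-plus-bump field scaled to +/-50 Hz; B1 maps default to a
constant 1.05.  Noise is seeded Gaussian or Rician
(`|S + n1 + i*n2|`); the Rician floor biases the fitted offset B upward
at low SNR, which is documented behaviour, not corrected.

What passing tests on these phantoms shows: the estimator chain recovers
known ground truth under the stated noise and field models.  What it does
not show: accuracy on real tissue, where exchange physics, motion, coil
inhomogeneity and reconstruction artifacts are present.

## Fitting

Per-voxel trust-region-reflective least squares on
`S(Tp) = A*exp(-Tp/T) + B` with the saturation image entering as `S = B`
(`exp(-inf) = 0`).  Initialization: B from the saturation image (else the
series minimum), A from `S(0) - B`, T from a log-linear regression of
`S - B` over the finite nonzero preparation times, clipped to bounds.
Bounds `T in [1, 2000]` ms, `A, B >= 0`; analytic Jacobian; tolerances
1e-8; at most 200 function evaluations.  A Gaussian (not Rician)
likelihood is used on magnitude data.  Voxels are independent — no
spatial regularization.  Degenerate voxels (non-finite, zero, or constant
series) are flagged `insufficient_signal`; estimates pinned at a bound
are flagged `at_bound` and excluded from `converged`.

**SD maps.** The standard error of T is
`sqrt(SSR/(n-3) * [(J'J)^-1]_TT) / c4(n-3)`.  The `c4` factor corrects
the severe small-sample downward bias of the residual SD: with the
five-contrast protocol the residual variance has only two degrees of
freedom, where the raw residual SD has expectation 0.886 sigma and median
0.83 sigma.  With the correction the median SD-map value tracks the
Monte-Carlo SD of the estimator to within a few percent across the
50-150 ms range (verified in the tests); at 1% noise the estimator is
unbiased to ~0.1% and its dispersion matches the Cramer-Rao bound from
the analytic Jacobian to ~1%.

## Statistics

All CV-type statistics use the sample (n-1) SD.  Per myocardial segment:
precision `wCV` averages (SD-map mean / TRAFF2 mean) over subjects and
repetitions; reproducibility `wCV_bar` averages over subjects the CV of
each subject's repetition means; inter-subject `CV_bar` is the CV of the
per-subject means.  The averaging order (average of CVs, not CV of
averages) is pinned here and in the tests because published conventions
vary.  Bland-Altman bias is `mean(y - x)` with limits of agreement at
+/-1.96 SD of the differences.  The 2SD scar threshold is remote mean
plus twice the remote SD.

AHA 16-segment labelling partitions the annulus from the anterior RV
insertion counterclockwise (6/6/4 sectors for basal/mid/apical; the first
sector counterclockwise of the insertion is the septal one), with a
chirality flag for mirrored data.  Group-inference tests (ANOVA, t-tests,
and friends) are deliberately delegated to standard statistics libraries.

## Problem sizes and determinism

Simulation problem sizes were chosen so the whole validation chain runs
comfortably on one CPU: inhomogeneity sweeps use single-voxel tissues with
192-sample waveforms, Monte-Carlo fitting checks use 1e4 voxels (bias/CRB)
and 500 replicates per ground-truth value (SD oracle), and the demo
pipeline uses a 64x64 grid.  Every stochastic call takes an explicit
integer seed and identical seeds give bit-identical outputs; artifact
directories carry the exact run configuration as YAML.

## Known limitations

* Bloch-mode absolute values are not tissue TRAFF2 (no exchange physics).
* Off-resonance deviations of the simulated composite element are steeper
  than scanner measurements on gel vials, whose relaxation-to-coherence
  balance is not recoverable from printed T1/T2 alone; only the direction
  and monotonicity of the trends are validated.
* The Rician bias of the magnitude-domain Gaussian fit is documented, not
  corrected.
* No motion, registration, coil sensitivity or k-space reconstruction
  effects are modeled.
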