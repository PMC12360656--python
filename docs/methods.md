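# Methods

`steerlqg` models continuous steering against a pseudorandom lateral
perturbation as a linear-quadratic-Gaussian (LQG) control loop with
delayed, noisy multisensory feedback, and provides the surrounding
pipeline: perturbation design, closed-loop simulation, frequency-domain
system identification, inverse-control parameter fitting, and a synthetic
study generator with known ground truth.

## Task and perturbation design

The controlled variable is the lateral position of a vehicle on a road.
A zero-mean sum of 12 sinusoids (0.1–1.93 Hz, velocity amplitude
0.1 m/s each, phases uniform on [0, 2π)) perturbs the vehicle's velocity.
Phase sets are redrawn until the summed signal stays within a 0.6 m/s
peak-speed cap (the motion platform's safety envelope); measured
acceptance probability is ≈ 2.6%, i.e. a few dozen redraws per trial, with
a 10,000-draw budget before the design is declared infeasible.  The cap is
checked on the un-enveloped sum over the whole active region, which bounds
the emitted signal everywhere since the envelope never exceeds 1.

A 145-s trial consists of a 5-s countdown (zero perturbation), a 5-s
linear ramp-up, a 120-s main window, and a 15-s linear ramp-down, sampled
at 60 Hz.  Only the main window is analyzed.  The ramp shape is a free
choice (the ramps are discarded before analysis); linear ramps are the
simplest monotone envelope.  Position is the left-rectangle integral of
velocity, matching the discrete velocity-controlled plant.

## Plant, sensory channels, and LQG synthesis

Core state (7 dimensions): vehicle position, velocity and acceleration
(p_v, v_v, a_v), wheel angle and angular velocity (p_w, v_w), and two
cascaded first-order neuromuscular stages (f_w, g_w; time constant
τ_nm = 40 ms) forming a second-order low-pass between the control command
and the wheel force.  The vehicle is velocity-controlled: v_v(t+1) =
λ·(p_w + Δt·v_w) + ε(t) with λ = 0.008 (m/s)/deg and ε the perturbation
velocity; acceleration is carried explicitly as the finite difference of
velocity because the vestibular (otolith) system senses acceleration.
A variant without the neuromuscular filter (control acts directly on wheel
force; 5 core states) isolates the filter's contribution to the loop's
phase lag.

**Force units.** The wheel equation is v_w(t+1) = v_w + Δt·m·f_w.  The
constant m is not identifiable jointly with the scale of the control
command u (the cost weighs r·u²), so it is a unit convention.  We set
m = 400 deg/s² per force unit, which makes typical commands O(1); with
that convention, compensation "turns on" for control-cost exponents
around r = 10^re, re ≈ −1, and all default parameter ranges (fit bounds,
synthetic-participant ranges) live on one consistent scale.  Motor noise
(σ_m) and the force-channel observation noise (σ_fw) are 0.01 — about 1%
of a typical command.

**Observations.** Visual channels deliver vehicle position and velocity
delayed 7 steps (≈117 ms); a vestibular/somatosensory channel delivers
vehicle acceleration delayed 1 step (≈17 ms) in the visuoinertial
condition and is absent (its observation row removed, not noise-inflated)
in the visual condition; proprioceptive channels deliver wheel angle,
velocity and force with no delay.  Delays are realized exactly by
full-state augmentation: the state is stacked with its previous
max-delay copies (7 × 8 = 56 dimensions by default) and each channel
reads its delayed copy, so one steady-state Kalman filter handles all
channels.

**Noise model.** All noise is additive Gaussian.  Channel base magnitudes:
0.005 m (visual position), 0.01 m/s (visual velocity), 0.10 m/s²
(vestibular acceleration), 0.1 deg / 1 deg/s / 0.01 (wheel channels).
A single free scale σ_s multiplies every sensory channel without changing
their ratios.  At the default σ_s = 1 the effective visual-position and
vestibular-acceleration noise equal the plausible magnitudes reported for
this class of task (0.5 cm, 10 cm/s²).  The estimator's one-step
prediction is additionally perturbed with σ_ξ = 0.01 on each core state,
and the motor command with σ_m through the second neuromuscular stage.

**Observer's model of the perturbation.** The filter treats the
sum-of-sines as white velocity noise with per-step variance equal to the
generator's power, Σᵢ Aᵢ²/2 = 0.06 (m/s)², entering through the same input
map as the true perturbation (velocity row 1, acceleration row 1/Δt).

**Synthesis.** The cost is E Σ (p_v² + r·u²) with r = 10^re.  Certainty
equivalence splits the problem: the feedback gain L solves the
infinite-horizon discrete LQR problem (independent of noise), and the
filtering-form steady-state Kalman gain K solves the dual Riccati problem
(independent of cost).  Both use `scipy.linalg.solve_discrete_are`; on the
rare ill-conditioned QZ reorderings (strong noise scalings such as
σ_s ≈ 2) a structured doubling iteration — quadratically convergent, and
verified against the Riccati residual — takes over.  Steady-state rather
than time-varying gains are used because the cost horizon is infinite and
trials are long relative to the loop's transients (closed-loop spectral
radius ≈ 0.9976, decay time ≈ 7 s, against a 120-s analysis window).

The joint system stacks the true state and the estimate with deterministic
part [[A, −BL], [KHA, A − BL − KHA]]; the perturbation and the three noise
sources enter through dedicated input maps.  Simulation iterates this
system at 60 Hz; the analytic frequency response evaluates the same loop's
transfer function from perturbation velocity to the wheel-commanded
("compensatory") vehicle velocity λ(p_w + Δt·v_w) at z = exp(i2πfΔt).

## Frequency-domain analysis

Gains and phases are obtained by exact-frequency least squares: sine and
cosine regressors at each design frequency (plus a DC term), fit jointly
over the analysis window.  The design frequencies are not integer
multiples of 1/120 Hz, so raw FFT bins would leak across components; the
joint projection is leakage-free and reduces to the FFT in the
commensurate case.  Compensatory gain is the amplitude ratio of the
wheel-commanded velocity over the perturbation velocity; relative phase is
their difference, wrapped to (−2π, 0] so that ideal compensation sits at
−π and increasing lag moves monotonically away from it without a branch
jump at the ideal point.  At the default operating point the loop's total
lag exceeds one turn across the design band, so *comparisons* of how close
two loops stay to −π use the analytically unwrapped phase (continuous in
frequency from near DC); the wrapped convention is retained for data
spectra, where only the 12 design frequencies exist.

Position RMSE is reported with per-window mean removal by default
(zero-mean RMSE), with RMS about the road center available via a flag;
windows are the full 120 s or its first/last halves.

Model-side signatures at the default operating point (all verified in the
test suite): the loop is low-pass; the visual-only condition lags strictly
more than the visuoinertial one above 0.1 Hz while their *gains* are
nearly identical at matched parameters — the gain contrast between
conditions emerges through the per-condition control-cost exponents (the
visual condition fits a larger r), not through the delay structure alone;
shrinking the visual delay mainly moves the visual condition's phase with
minimal gain effect; removing the neuromuscular filter moves phase toward
−π with almost no gain change.

## Inverse-control fitting

Free parameters θ = {σ_s, re_vis, re_visuo}: the shared sensory-noise
scale and one control-cost exponent per condition.  All other parameters
are fixed.

The fitted quantity is the model's *expected one-step-ahead wheel angle
given the previous angles*.  The closed loop driven by the known
perturbation sequence is itself linear-Gaussian, so conditioning on the
recorded wheel-angle history is one more Kalman filtering problem: a
steady-state filter on the 112-dimensional joint [x; x̂] system whose only
measurement is the recorded wheel angle.  The assigned measurement
variance is a numerical regularizer (10⁻⁹ deg²) because synthetic
recordings are exact; for quantized hardware recordings the sensor's
quantization variance (0.06²/12 deg²) can be passed instead.  This choice
matters: assuming measurement noise comparable to the innovation variance
biases the fitted σ_s upward.  On data the model itself generated without
noise, the prediction reproduces the recorded wheel angle to machine
precision, so the objective's floor is exactly zero there.

The objective pools the squared prediction errors over the analysis
windows of all experimental trials of both conditions (each condition
using its own exponent) and takes the square root — a wheel-angle RMSE in
degrees.  Practice trials are excluded.  Full-length 120-s windows are
required in practice: the inference filter takes tens of seconds to lock
onto the participant's internal estimator state, and with short windows
that transient dominates the objective and favors over-smoothed models.
Recovery experiments therefore scale down trial *counts*, never window
length.

Optimization uses bounded Powell direct search (σ_s ∈ [0.05, 20] searched
in log10, exponents in [−6, 2]) from three fixed start points, keeping the
best.  The search directions take the exponents before log σ_s: with a
wrong exponent the σ_s direction is misleadingly flat-to-decreasing and a
σ_s-first line search can run to the bound.  The procedure is fully
deterministic.  Verified recovery at θ* = (1.0, −1.0, −1.5) from 10 noisy
trials per condition: σ̂_s = 0.97, r̂e = (−1.02, −1.51).

## Synthetic study

The generator emulates the full design: 22 participants × 2 conditions ×
(1 practice + 10 experimental) 145-s trials, condition order
counterbalanced by participant parity.  Per-participant true parameters:
σ_s log-uniform on [0.5, 2]; re_visuo uniform on [−2, −0.5]; re_vis =
re_visuo + Δ with Δ uniform on [0, 1], so the visual condition always
carries the higher control cost — the direction of the fitted exponents —
which reproduces the study's headline contrast (lower RMSE and higher
high-frequency gain with visuoinertial feedback).  These ranges are chosen
for recovery testing, not demographic realism.

All randomness derives from one global seed through hierarchical
sub-seeds keyed by (participant, condition, trial), so regeneration is
byte-identical and a smaller study reproduces the first participants of a
larger one exactly.  Trials are written as CSV (unit-tagged columns,
`%.17g` floats for lossless round trips) with a JSON sidecar holding
condition, seeds, phases, timeline markers, units and the full model
configuration; a manifest records participants, true parameters and file
paths.

## What the synthetic data do and do not show

The generator produces exactly the model's own behavior plus its assumed
noise.  Passing recovery and contrast tests therefore validates the
pipeline's internal consistency — the estimator, analysis and fitting
machinery recover what was put in — but cannot validate the model against
human steering: real participants may predict the quasi-periodic
perturbation rather than treat it as white noise, adapt within or across
trials, or use strategies outside the LQG family.  Mis-specification
beyond the neuromuscular-filter variant is out of scope.

## Numerical choices and problem sizes

- Riccati equations: scipy QZ solver with a structured-doubling fallback
  (tolerance 1e-14 relative step, residual-checked).
- Time-domain vs analytic cross-checks use a 30-s ramp-up so start-up
  transients decay below the 1% comparison tolerance before the analysis
  window; with the standard 5-s ramp the residual transient reaches ~6% at
  the highest, weakest-responding frequencies.
- Test-suite problem sizes: fit recovery uses 10 trials/condition at full
  length with three Powell starts (maxfev 120 each); study I/O tests use
  shortened (20–30 s) main windows, which leave design counts unchanged;
  the full 440-trial study is generated once with 20-s main windows.
- Degenerate inputs: an all-zero perturbation at a design frequency makes
  gain undefined and raises; frequencies at/above Nyquist raise; unstable
  joint systems are refused with the spectral radius in the message.

## Known limitations

- σ_s is weakly identified near the default noise level: the closed-loop
  response changes by <1% between σ_s = 0.2 and 1, so recovered values
  lean on the prediction-error structure rather than the response shape,
  and recovery degrades for participants whose true σ_s sits in that flat
  region with few trials.
- The sled/screen hardware is modeled as unity; the 45° linear-wheel and
  small-angle assumptions are inherited from the task design.
- Fitting assumes the recorded wheel angle is exact; heavily quantized or
  filtered recordings need the measurement-variance argument adjusted.
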