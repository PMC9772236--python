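# Methods

This note documents the models, the preprocessing rules, the synthetic-data
generator and the numerical choices made in `pupilhgf`, in enough detail to
judge what the package's tests do and do not establish.

## Task and data model

The package targets a virtual-reality interception task: on each trial a
ball is released, bounces, and is struck; the ball is either a *normal*
bounce (`u = 1`) or an unexpectedly *bouncy* one (`u = 0`), and the
probability p(normal) shifts among 0.5, 0.67 and 0.83 in segments, creating
a volatile environment. Two kinds of raw signal are analysed per trial:

* **gaze** — head-centred pitch/yaw in degrees at 120 Hz with validity
  flags, segmented from ball release to racquet contact. The pitch of the
  final pre-bounce fixation indexes where the participant expects the ball
  to go (lower gaze = expecting the lower, normal bounce).
* **pupil** — binocular diameter in mm at 90 Hz; blinks appear as runs of
  zero diameter.

## Perceptual and response models

### Binary Hierarchical Gaussian Filter

Level 1 is the outcome; level 2 a Gaussian random walk on the outcome
tendency `x2` (logit of p(normal)) with step variance `exp(kappa*mu3 + omega)`;
level 3 a random walk on log-volatility with variance `theta = exp(log_theta)`.
The variational update used per trial is the standard closed form for
binary inputs (time step 1): prediction `mu1hat = sigmoid(mu2)`, prediction
error `delta1 = u − mu1hat`, precisions
`pihat2 = 1/(sigma2 + exp(kappa*mu3 + omega))`,
`pi2 = pihat2 + mu1hat(1−mu1hat)`, posterior `sigma2' = 1/pi2`,
`mu2' = mu2 + sigma2'*delta1`, volatility prediction error
`delta2 = (sigma2' + (mu2'−mu2)^2)*pihat2 − 1`, and the level-3 update with
weight `w2 = exp(kappa*mu3+omega)*pihat2`. The 4-level variant replaces the
level-3 step variance with `exp(kappa3*mu4 + omega3)` and closes level 4
with `exp(log_theta4)`; setting `kappa3 = 0, omega3 = log_theta` reduces it
exactly to the 3-level filter (unit-tested).

Two derived trajectories drive all pupil analyses:

* `eps2(k) = sigma2(k) * delta1(k)` — the precision-weighted prediction
  error (exactly the level-2 update step, so `sum eps2 = mu2(K) − mu2(0)`
  holds to machine precision; this telescoping identity is a test).
  Regressions use `|eps2|` by default (pupil dilation tracks unsigned
  surprise); signed mode is available (`eps_mode="signed"`).
* `alpha(k) = sigma2(k)` — the trial-specific learning rate (the gain on
  `delta1`). This is the adopted definition of the "learning rate"
  trajectory; it is a convention choice, exposed as such.

A filter update that produces a non-positive precision or non-finite state
raises `InstabilityError` with the trial index; during fitting such
parameter points get objective value +inf (rejected), never silent NaNs.

### Response model

The unit-square sigmoid maps the predicted probability to a response
probability `P(y=1) = m^zeta / (m^zeta + (1−m)^zeta)` with decision noise
`zeta > 0`; `m = 0.5` is its fixed point for every `zeta`, and `zeta → inf`
is the deterministic limit. Missing responses contribute nothing to the
likelihood while inputs still drive the filter.

### Rescorla–Wagner comparator

`v(k) = v(k−1) + alpha*(u(k) − v(k−1))` with fixed learning rate
`alpha ∈ (0,1]`, responses through the same unit-square sigmoid. With
constant input the closed form `v(k) = 1 − (1−v0)(1−alpha)^k` is tested
against the iteration.

## Estimation and model comparison

Parameters carry independent Gaussian priors in an unconstrained
estimation space: identity for `omega`, `omega3` and initial means; log for
`theta`, initial variances and `zeta`; logit for the R-W `alpha` and `v0`.
Defaults (estimation-space mean, variance): `kappa` (1, 0 — fixed),
`omega` (−5.6, 8), `log_theta` (−4, 0 — fixed), `mu2_0` (0, 8),
`log sigma2_0` (log 0.1, 1), `mu3_0` (1, 8), `log sigma3_0` (0, 1), the
analogous level-4 rows for the 4-level model with `omega3` (−5.6, 8) and
`log_theta4` (−4, 0), `log zeta` (log 48, 1), R-W `logit alpha` (0, 1) and
`logit v0` (0, 1). `kappa` is fixed to keep the model identifiable with
relatively few trials. All are overridable via `ParamSpec`.

MAP estimation minimises the negative log joint with BFGS from the prior
mean plus perturbed restarts (default SD 0.5 in estimation space, ties
broken by lower objective then smaller parameter norm; deterministic given
a seed). The log-model evidence is the Laplace approximation
`lme = −nlj* + (d/2)log(2π) − (1/2)log det H`, with `H` the central-finite-
difference Hessian (step 1e−4; steps 1e−5 and 1e−3 are tried when the MAP
sits against an instability boundary; an indefinite `H` is repaired by
clipping its eigenspectrum to a positive floor and the fit flagged). Group
comparison is fixed-effects: LMEs sum over participants and differences
exponentiate into Bayes factors. Identifiability is checked by averaging
the Laplace-posterior correlation matrices across participants and
flagging |r| > 0.8.

The "simulated Bayesian observer" predictor set is obtained by running the
3-level filter forward at the prior means on each participant's own input
sequence — no fitting.

## Gaze pipeline

Per trial: three-frame median smooth (endpoints unchanged), zero-phase
2nd-order 15 Hz Butterworth low-pass (the dual pass squares the magnitude
response, so a cutoff-frequency sinusoid emerges at half amplitude — a
test), trial QC (exclude >20 % invalid samples or any invalid run
>100 ms), I-DT fixation detection (window grows while pitch range + yaw
range ≤ 3°, minimum span 100 ms; windows never cross invalid samples;
verified against an exhaustive brute-force oracle), selection of the
latest fixation ending within 400 ms before the bounce, participant-level
outlier flagging (|z| > 3.29 → missing) and exclusion (missing + outliers
> 15 %). The per-trial fixation pitch is then discretized: a change below
−1 SD of all trial-to-trial changes (SD pooled over the session, n−1
convention) is `y = 1` (gaze moved lower → expecting normal), above +1 SD
is `y = 0`, sub-threshold changes carry the previous response forward
(`carry=False` leaves them missing), the first trial is missing.
Discretization is invariant to shifting and positive rescaling of pitch.

Caveat found while characterising the discretization: when a response
series is nearly constant (one response category ≪ 10 % of trials), the
rare category's pitches sit >3.29 SD from the mean and are removed as
"outliers", and the 1-SD change threshold is then dominated by noise. The
rule behaves well for response series with both categories reasonably
represented, which is what volatile schedules produce.

## Pupil pipeline

Per eye: blinks = maximal zero runs padded by 150 ms (merged when
overlapping); trial QC on pre-interpolation missingness (a sample is
missing when either eye reads zero; >20 % missing or a run >100 ms
excludes the trial — interpolated samples are not data); linear
least-squares interpolation over 100 ms flanks (edge gaps hold the nearest
valid value); zero-phase 2nd-order 10 Hz Butterworth. Eyes are then
averaged (an entirely-dead eye triggers a flagged monocular fallback). The
task-evoked pupil response (TEPR) is the maximum over [0, 3 s] after ball
release minus the mean over the 200 ms pre-release baseline; stimulus
onset = ball release (configurable). Each participant's TEPRs are divided
by their n−1 SD (values are "SDs of response"), outliers (|z| > 3.29)
become missing, and participants with >15 % missing + outliers are
excluded. Trials whose trace does not cover the full baseline + response
window are excluded rather than truncated.

## Group statistics

Per participant and predictor (`mu2`, `mu3`, `|eps2|`, `alpha`; personalised
and simulated sources), the normalized TEPR series is regressed on the
z-scored predictor by iteratively reweighted least squares with Tukey
bisquare weights (tuning constant 4.685, tol 1e−6, ≤50 iterations;
statsmodels RLM), pairwise-deleting missing trials and requiring ≥10
complete pairs. The slope is the β weight (SD pupil per SD predictor).
β samples are Winsorized once (|z| > 3.29 replaced by the next-most-
extreme value made 1 % more extreme in magnitude, z from the original
sample), then tested with one-sample t-tests (`d = t/√n`; paired t-tests
compare personalised vs simulated β). Bayes factors are the default
two-sided JZS value for one-sample designs (Cauchy(0, 0.707) prior on the
standardized effect, evaluated by adaptive quadrature of the
scale-mixture integral); BF labels use cut points 0.1 / 0.33 / 3 / 10.
The sensitivity analysis inverts the noncentral-t power function
(one-tailed by default — the convention consistent with all three quoted
minimal-d values; `tails=2` available) by bracketed root finding to 1e−6.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions for every property test:

* **Schedules** — two counterbalanced orders: 12-trial segments cycling
  0.5 → 0.83 → 0.67 → 0.83 → 0.5 → 0.67 (order A; order B reversed) over
  2 blocks × 72 trials; ball types are independent Bernoulli draws within
  segments (a fixed-ratio mode exists but is not default).
* **Agents** — 3-level HGF forward runs with `omega ~ Normal(−5.6, 1)` and
  `zeta` log-normal(log 3, 0.3), responses sampled through the unit-square
  sigmoid. The `zeta` default was chosen so agents emit variable, partly
  stochastic responses with both categories well represented (deterministic
  agents produce nearly constant response series, which no discretization
  of relative gaze shifts can recover — see the caveat above).
* **Gaze traces** — 120 Hz, 0–1.8 s; pursuit ramps, a stationary fixation
  in [0.75, 1.05] s (bounce at 1.2 s) whose pitch maps the agent's binary
  commitment linearly between −10° (bouncy) and −20° (normal), fast
  post-bounce chase; white measurement noise (default SD 0.3°, typical of
  VR eye trackers) and optional invalid-sample dropouts.
* **Pupil traces** — 90 Hz, −0.3–3.2 s; 3 mm baseline + slow sinusoidal
  drift (0.02 mm) + gamma-shaped event kernel (shape 3, unit peak at 1 s
  after release) scaled by a per-trial amplitude, plus binocular
  zero-valued blinks (Poisson rate 0.1/trial, 60–200 ms). The amplitude in
  SD-units is `base (2.0) + beta_eps * z(|eps2|) + beta_alpha * z(alpha) +
  Normal(0, pupil_noise_sd)`, converted to mm at 0.1 mm per unit. The
  realized amplitude is stored as ground truth, so extraction fidelity is
  testable exactly.

`simulate_feature_cohort` produces the identical ground truth (same seeds,
same draws) without synthesising traces. The replicate-heavy calibration
properties (200-replicate null calibration, 100-replicate power at
n = 35) run at this feature level; the trace → TEPR stage they skip is
deterministic by construction (peak = amplitude up to sample
discretization) and is verified separately by exact kernel-peak tests and
a full end-to-end run (ground-truth amplitude vs extracted normalized
response, r > 0.95 with blinks and drift active).

What the generator does **not** emulate: luminance effects (the task
environment has constant luminance), pupil foreshortening, saccade/pursuit
kinematics beyond simple ramps, head movement, and any dependence of gaze
noise on eccentricity. Passing tests therefore demonstrate that the
pipeline recovers the structure this generator encodes — event-locked
amplitudes coupled to model quantities, fixation-encoded binary
responses — not that real eye-tracking artefacts are handled beyond the
stated blink/dropout/QC models.

## Numerical choices and edge cases

* Filters: `scipy.signal.filtfilt`; traces shorter than the filtfilt pad
  length pass through unfiltered rather than erroring.
* `sigmoid` and the unit-square likelihood are computed in log space with
  predictions clipped to [1e−12, 1−1e−12].
* Degenerate inputs raise early with specific messages: non-binary u,
  zero-variance pitch changes, all-zero pupil traces, constant regression
  predictors, zero-SD normalization.
* Fit determinism: all stochastic steps (restart perturbations, agent
  sampling, schedule draws) flow from explicit integer seeds.
* Statistical calibration under the generator's null (`beta_eps = 0`) is
  measured by the test suite and the acceptance script over 200 replicate
  experiments at n = 35: the group test on |eps2| β weights rejects at a
  rate close to the nominal 5 %. Because a 200-replicate rate estimate has
  a standard error near 1.6 %, the suite asserts binomial compatibility of
  the observed count with a true rate in 5 ± 2.5 % rather than bounding
  the raw count. Any mild residual inflation traces to bisquare IRLS with
  a skewed predictor at 144 trials, not to the t-test.

## Known limitations

* Fixed-effects (summed-LME) model comparison only; no random-effects
  model selection, no MCMC posteriors.
* The Laplace LME is exact only for locally quadratic joints; heavily
  non-Gaussian posteriors (e.g. near-boundary `alpha`) are approximated.
* The I-DT detector cannot find fixations when post-filter sample noise
  approaches the dispersion threshold (white trace noise ≳1.5° at the 3°
  threshold); such trials are reported missing rather than guessed.
* One printed-value check is knowingly irreproducible from its printed
  inputs at the stated tolerance (see the test suite's Bayes-factor
  parametrization); the computation is cross-validated against an
  independent implementation on the other cases.
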