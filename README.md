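# pupilhgf

Hierarchical Bayesian modelling of anticipatory eye movements, with
pupil-linked readouts of surprise.

`pupilhgf` is for researchers studying how people learn the statistics of
a volatile environment from their predictive behaviour — here, a
ball-interception task in which a ball is either a *normal* bounce
(`u = 1`) or an unexpectedly *bouncy* one (`u = 0`) and p(normal) shifts
among 0.5, 0.67 and 0.83 over time. Where participants look just before
the bounce reveals what they expect; how their pupils dilate after the
event reveals how surprised they were. The package implements the full
analysis chain:

1. **Trial design** — volatile binary schedules in counterbalanced orders
   (`design`).
2. **Gaze pipeline** — median smooth, 15 Hz zero-phase Butterworth, I-DT
   fixation detection (3°, 100 ms), pre-bounce fixation selection
   (< 400 ms), QC (20 % / 100 ms / 3.29 SD / 15 % rules), and 1-SD
   discretization of pitch changes into binary responses `y` (`gaze`).
3. **Pupil pipeline** — blink repair (zero runs padded 150 ms, linear
   interpolation), 10 Hz filtering, binocular averaging, baseline-corrected
   peak response over 3 s, SD normalization, QC (`pupil`).
4. **Learning models** — 3- and 4-level binary Hierarchical Gaussian
   Filters and a Rescorla–Wagner comparator, with the unit-square sigmoid
   response model (`hgf`); MAP fitting with quasi-Newton optimization,
   Laplace log-model evidence, fixed-effects Bayes-factor model comparison
   and identifiability checks (`fitting`).
5. **Group statistics** — per-participant robust (bisquare) regressions of
   normalized pupil responses on `mu2`, `mu3`, `|eps2|` and the learning
   rate `alpha`, Winsorizing, one-sample/paired t-tests with Cohen's
   `d = t/sqrt(n)`, JZS Bayes factors, and a noncentral-t sensitivity
   analysis (`stats`).
6. **Synthetic cohorts** — a generator producing raw gaze/pupil traces with
   known ground truth, so the whole chain is testable with no real data
   (`synthetic`), plus an end-to-end orchestrator and CLI (`pipeline`,
   `cli`).

## The model in brief

The binary HGF stacks Gaussian random walks: level 2 tracks the tendency
`x2` (logit of p(normal)) with step variance `exp(kappa*mu3 + omega)`;
level 3 tracks volatility. One trial's update gives the prediction
`mu1hat = s(mu2)`, prediction error `delta1 = u − mu1hat`, and posterior
`mu2' = mu2 + sigma2'*delta1`. The quantities related to pupil dilation
are the precision-weighted prediction error `eps2 = sigma2*delta1` and the
learning rate `alpha = sigma2`. Responses follow the unit-square sigmoid
`P(y=1) = mu1hat^zeta / (mu1hat^zeta + (1−mu1hat)^zeta)`. Models are
scored by Laplace log-model evidence and compared with
`BF = exp(LME_A − LME_B)` summed over participants.

## Worked example

Fit a 3-level HGF to one simulated participant's input/response series:

```python
from pupilhgf import BinaryHGF, HGFParams, generate_schedule, simulate_agent_responses

schedule = generate_schedule(order_id="A", seed=7)        # 2 blocks x 72 trials
truth = HGFParams(omega=-4.5, zeta=3.0)
y, _ = simulate_agent_responses(schedule, truth, seed=7)  # anticipatory responses
result = BinaryHGF(schedule.u, y, levels=3).fit(n_restarts=3, seed=0)
print(result.summary())
```

```
Model: hgf3   trials: 144   responses: 144
neg log joint: 64.6722   LME (Laplace): -62.9240   converged: True
parameter  estimate    space status  prior_mean  prior_var
    kappa    1.0000 identity  fixed      1.0000     0.0000
    omega   -5.1414 identity   free     -5.6000     8.0000
log_theta   -4.0000 identity  fixed     -4.0000     0.0000
    mu2_0   -0.0400 identity   free      0.0000     8.0000
 sigma2_0    0.0800      log   free     -2.3026     1.0000
    mu3_0    1.4586 identity   free      1.0000     8.0000
 sigma3_0    1.0023      log   free      0.0000     1.0000
     zeta    3.1905      log   free      3.8712     1.0000
```

The generating `omega = −4.5` is recovered as −5.1 under the (wide,
mean −5.6) prior; `result.trajectory` carries the per-trial `mu1hat`,
`mu2`, `sigma2`, `mu3`, `eps2` and learning-rate series used as pupil
predictors, and `result.lme` feeds model comparison.

Run the whole pipeline on a synthetic cohort (raw traces are generated,
preprocessed, fitted and analysed; β weights are SD of pupil response per
SD of predictor):

```python
from pupilhgf import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(n_participants=6, seed=42,
                                     outdir="out", n_restarts=2))
print(bundle["comparison"].summary())
print(bundle["group_stats"][["source", "predictor", "mean_beta", "t", "p", "bf10"]])
```

```
Model comparison over 6 participants (fixed effects, 0 dropped)
      summed_lme  delta_lme
hgf3     -415.43      -0.05
hgf4     -415.39       0.00
rw       -427.21     -11.82

      source predictor  mean_beta      t     p       bf10
personalised  alpha_lr      0.116  1.464 0.203      0.784
personalised      eps2      0.782  6.130 0.002     26.871
...
```

Both hierarchical models beat the fixed-learning-rate model by ~12 log
units (the 3- and 4-level variants are near-equivalent here, as expected
when level-4 volatility adds nothing), and the generator's built-in
coupling of pupil amplitude to |eps2| (0.5 SD per SD) is recovered as a
significantly positive β with strong Bayes-factor support.

The same pipeline runs from the shell:

```bash
pupilhgf simulate --n-participants 6 --seed 42 --out raw/   # write raw traces
pupilhgf validate raw/                                      # schema checks
pupilhgf run --input-dir raw/ --seed 42 --out results/      # full analysis
```

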