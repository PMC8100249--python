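# Methods

## Problem setting

The package implements an offline analysis of continuous locomotion-mode
recognition under varying task anticipation.  The unit of classification is
a sliding, overlapping analysis window of multichannel kinematics; the
classifier is a linear discriminant; evaluation is per-subject leave-one-out
over trials, with all time-resolved results synchronized at the first
trailing-leg toe off (TTO1), the instant the locomotor transition begins.
Because no recorded dataset ships with the package, a synthetic cohort
generator stands in for data collection; its defaults encode the emulated
study design (5 subjects, 5 trials per task × anticipatory state, 58
kinematic channels at 120 Hz).

## Synthetic signal model

Per channel `c` and sample `t` of a trial:

```
x(t) = base_c(φ(t)) + D[task, state, c] · g(t) · s(t) + η_c · g(t) · s(t) + u_c + ε(t)
```

* **Base waveform** `base_c(φ)`: a 3-harmonic Fourier series over gait phase
  φ, with 1/h spectral decay.  φ is piecewise-linear between the trial's
  gait events and extrapolated with edge slopes, so waveforms stay
  event-aligned across trials with jittered event times.  The coefficients
  are drawn once from a constant internal seed: they play the role of the
  fixed biomechanics of gait, while the cohort seed varies subjects, event
  timing and noise.
* **Deviation patterns** `D`: each task has an anticipated and an
  unanticipated pattern over channels, also fixed geometry.  The anticipated
  patterns are built from a dense "cut" component (amplitude 0.35 per
  channel), a cut-style difference making crossover and sidestep correlate
  at 0.97 (the two styles share almost their whole signature — the source of
  their mutual confusion), and a dense stair component (amplitude 0.6) whose
  COS and SSS versions correlate at 0.6 (the stair approach differs by entry
  style).  Walking has zero deviation.  The unanticipated pattern of a task
  adds a dense task-generic compensatory shift (amplitude 0.5), a
  task-specific execution difference at half scale reusing the same
  similarity geometry, and expresses only 55 % of the stair component:
  reactive execution completes the stair preparation partially, which is
  what parks unanticipated mixed transitions between their own class and
  their level-ground counterpart under anticipated-only training.
* **Anticipation gate** `g(t)`: ramps 0 → 1 from THS1 over 250 ms for
  anticipated trials (preparation complete well before TTO1) and from the
  cue over 4 × 250 ms for unanticipated trials (reorganization without
  preparation is slow, so the deviation is still incomplete when the
  transition starts).
* **Stair gain** `s(t)`: 1 everywhere except after LTO2 in mixed
  transitions, where it becomes 1.6 — stair ascent recruits larger
  multi-plane joint excursions.
* **Trial-level execution variability** `η`: drawn once per trial per
  channel, SD 0.1 for anticipated and 0.35 for unanticipated trials, and
  gated together with the deviation.  This is the term that makes
  unanticipated trials mutually dissimilar, so a single training bout is
  informative but not fully representative of another unanticipated trial.
* **Subject offsets** `u`: N(0, 0.5²) per (subject, channel), constant
  across a subject's trials — the minimal mechanism that makes per-subject
  leave-one-out meaningful.
* **Noise** `ε`: white Gaussian, SD 1.0, optionally AR(1)-colored
  (coefficient 0 by default).

Event timings (ms, mean ± jitter SD): THS1 100 ± 20, cue 400 ± 30
(unanticipated only, constrained to [THS1, TTO1)), TTO1 700 ± 30, THS2
1300 ± 40, LTO2 1500 ± 40 and THS3 2100 ± 50 (mixed only).  Unanticipated
trials use 1.5× the jitter SDs — reacting to a randomized cue is temporally
more variable than executing a plan.  Trial tails after the last event make
walking trials structurally shortest and mixed transitions longest, which
exercises the shortest-trial truncation rule of the error curves.  Draws
violating the event ordering are retried up to a bound, then fail loudly.

### Calibration of the defaults

Amplitudes, correlations, ramps and noise scales are not observable design
constants, so they were calibrated once so that the pipeline lands in the
qualitative accuracy regime the analysis is about — anticipated accuracy in
the high 80s–100 with residual crossover/sidestep confusion; unanticipated
Zero-Trial accuracy collapsing for mixed transitions and mediocre for single
cuts; large recovery from one or two target-task bouts, strongest for mixed
transitions; comparable but imperfect All-UA and UA-A performance — and then
frozen.  A pure gate-timing model (unanticipated execution as a delayed copy
of the anticipated pattern) cannot produce this regime: the anticipated
trials' own onset ramp teaches an anticipated-only classifier the entire
partial-amplitude path, and whatever errors remain concentrate at low gate
values where no training bout helps.  The state-specific execution patterns
and the attenuated unanticipated stair component above are therefore load-
bearing model features, not tuning conveniences.

### What the generator does not emulate

Marker-level measurement, inverse-kinematics artifacts, ground-reaction
forces, muscle activity, within-trial mode switching, fatigue or learning
across trials, and any physical IMU error model.  Class-conditional
distributions are unimodal around a gated mean trajectory; real gait is
multimodal across strides.  Passing results on synthetic cohorts therefore
demonstrate the correctness and the qualitative behavior of the analysis
machinery, not field performance of any classifier.

## Windowing and features

Milliseconds convert to samples by round-to-nearest at the trial sampling
rate; at 120 Hz the nominal 300 ms / 25 ms map exactly to 36 / 3 samples.
Windows advance from the start of the recorded signal; the last window is
the last fully contained one, giving `floor((n − L)/s) + 1` windows.  A
window is timestamped at its end — the causal instant a controller could
act on it — and a window whose half-open span ends exactly at the TTO1
sample has time 0.  Standard deviation uses the n−1 denominator.  Every
window inherits the whole trial's task label; no within-trial label
switching exists in this design.

## Discriminant

Features are standardized per feature with center/scale learned on the
training split only (channels mix m/s², deg/s and deg).  The pooled
within-class covariance uses the N−K denominator and diagonal-target
shrinkage Σ_λ = (1−λ)Σ + λ·diag(Σ) with λ = 0.01 by default — with 348
features (58 channels × 6) and tens of training trials the unshrunk Σ is
typically singular.  λ = 0 is allowed and raises a singularity error
naming the remedy when Σ cannot be factorized.  Zero diagonal entries
(degenerate constant features) are floored at 1e−12 of the largest entry
to preserve positive definiteness.  Priors are uniform over the classes
present, since trial lengths — hence window counts — differ by task.
Ties in the argmax resolve to the earlier class in the canonical order
(W, CO, SS, COS, SSS).

The leave-one-out sweep fits hundreds of heavily overlapping training
pools, so the evaluation engine caches per-trial sufficient statistics
(window count, feature sums, Gram matrix); any pool's standardizer, class
means and pooled covariance are exact linear combinations of these, making
a fit one Cholesky factorization instead of one pass over the windows.  A
test asserts the fast path equals the direct fit.

## Paradigms and evaluation

Pools are subject-specific, rebuilt per held-out trial, and never contain
the test trial.  "Target task" in One-/Two-Trials means the task of the
held-out trial; bouts are drawn without replacement from the subject's
remaining unanticipated trials of that task using a seeded RNG keyed by the
bout-selection seed and the test trial id.  Training uses all windows of
the pool trials, including pre-TTO1 windows — continuous classification
requires the model to know pre-transition patterns — while accuracy counts
only windows ending at or after TTO1.  Anticipated, unanticipated and
walking test trials are all evaluated under every paradigm for symmetric
reporting.  Per-subject results are aggregated first (per-trial accuracies
averaged within subject), then averaged across subjects.  Overall accuracy
is reported both window-pooled across tasks and as the unweighted mean of
per-task accuracies.

Error-vs-time curves anchor each trial at its first window ending at or
after TTO1, average the 0/100 indicators across trials at each grid
position (grid step = the window increment), truncate to the span covered
by every contributing trial, and carry across-trial mean event times for
annotation.  Event-time jitter across trials means grid positions align
windows by ordinal distance from the anchor, not by identical absolute
times; with 25 ms increments the misalignment is below half an increment.

## Statistics

Accuracy tables indexed by (subject, task, paradigm, window length) feed a
two-way fixed-factor ANOVA (statsmodels OLS, type-II sums of squares) with
Shapiro–Wilk on the residuals and, for factors significant at α = 0.01,
Bonferroni-corrected pairwise t-tests pooled over the other factor.  Cell
balance is validated before fitting.  A constant response (a perfect fit
with zero residual) makes F undefined; the harness reports no effects in
that degenerate case rather than dividing by zero.  Post-hoc statistical
power analysis is out of scope.

## Reproducibility

All randomness descends from explicit integer seeds; (config, seed)
determines a cohort bit-for-bit.  The CLI derives independent per-stage
seeds from the master seed by hashing the stage name into a seed sequence,
so stages can be re-run alone.  Trial CSVs are written with 17 significant
digits and parsed with round-trip float precision, so file round-trips are
bit-exact.

## Problem sizes

Tests and the acceptance script run the full emulated design — 5 subjects,
5 trials per condition, 58 channels, the nominal 300 ms window — for the
headline comparisons, and the directional claims are asserted over 10
seeded cohort replicates.  The full 21-length window sweep is exposed
through the CLI but exercised in tests only at representative lengths; the
sufficient-statistics fit path keeps a complete five-paradigm evaluation of
one cohort near ten seconds.

## Known limitations

* The discriminant assumes shared covariance and unimodal classes; the
  generator satisfies this roughly but real windowed gait features do not.
* The single shrinkage default (0.01) was chosen for the 348-feature
  regime; much smaller channel sets may prefer λ closer to 0.
* Error-curve alignment is ordinal (window counts from the anchor), not
  absolute-time interpolation.
* The synthetic cohort fixes the task geometry across seeds; conclusions
  about variability across *geometries* would need the geometry seed
  exposed and varied.
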