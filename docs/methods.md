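# Methods

This note records the scientific conventions, models and numerical choices
behind `locomod`, in the package's own terms. It is the reference for what
each analysis computes, why the defaults are what they are, and where the
known limitations lie.

## 1. Data model

The unit of analysis is a **session**: simultaneous ΔF/F traces for a
population of neurons at 30 Hz, a running-speed trace (cm/s), a pupil trace
(a.u.), and a stimulus epoch table. The stimulus protocol is a leading
spontaneous (mean-luminance) block followed by drifting gratings — 8 motion
directions (0°–315° in 45° steps) × `n_reps` repetitions, each 2 s of
stimulus separated by 1 s blanks, in random order with a random temporal
frequency from {1, 2, 4, 8, 15} Hz.

### ΔF/F baselining

Raw fluorescence is converted to ΔF/F against a rolling **mean-of-mode**
baseline: at each frame, the baseline is a centred rolling mean (3000
frames ≈ 100 s) of a centred rolling mode (5400 frames ≈ 3 min) of the
trace, with windows truncated (not padded) at the edges. The mode of a
real-valued trace is taken after discretising amplitudes at 10⁻³ of the
trace median, with ties resolved to the smallest value. Expressing the
resolution as a fraction of the median makes the result exactly invariant
to multiplicative rescaling of the raw trace (photomultiplier gain,
expression level), which the tests assert bit-for-bit.

### Trials and locomotor state

The per-trial response is the mean ΔF/F over a 2 s window starting 10
frames after grating onset (indicator-rise latency); the window may run
into the following blank and a trial is only dropped if the window runs
past the end of the recording. Each trial is labelled from its window of
speeds:

* **running** — mean speed > 3 cm/s and speed never below 0.5 cm/s;
* **stationary** — mean speed < 0.5 cm/s and speed never above 3 cm/s;
* **ambiguous** — everything else (state transitions inside the window);
  ambiguous trials are excluded from all state-conditioned analyses.

Before any state comparison, trial counts are **balanced**: every
(direction, state) cell is subsampled without replacement to the global
minimum cell count, so both state decoders and both per-state reliability
estimates see identical trial numbers per stimulus. A session in which any
cell is empty (the animal essentially never ran, or never sat still) is
excluded.

## 2. Behavioral-state tuning

A neuron's tuning curve to a covariate (running speed or pupil diameter)
is its mean activity in 20 quantile bins of the covariate (equal-width
binning is available; duplicate quantile edges from heavy ties — e.g. a
large mass at zero speed — are merged). Significance has two independent
axes:

* **Variance test** — Levene's test (centre = mean), one-sided: the real
  binned curve must be *more* variable across bins than the curve obtained
  after randomly permuting the activity trace against the covariate. By
  default a single permutation is drawn (`n_perm=1`); with more, the
  median p across permutations is reported, a deliberately conservative
  variant. The default is 1 because the median-p variant is *not*
  calibrated: on white-noise activity, median-of-100-permutations rejects
  at ≈0.009 instead of the nominal 0.05, while the single-permutation form
  rejects at ≈0.05.
* **Monotonicity** — Spearman's rank correlation between bin centres and
  the binned curve. At α = 0.05: significant positive rho → `positive`,
  significant negative rho → `negative`; otherwise a significant variance
  test → `nonmonotonic`; else `untuned`.

A constrained three-Gaussian model comparison localises non-monotonic
tuning: Gaussians whose centre is bounded above the covariate range
(monotone increasing on the data), below it (decreasing), or inside it
(interior bump) are fit to training-half tuning curves by bounded least
squares and scored on held-out curves over 10 random 75/25 splits; the
lowest mean CV error wins, with ties broken toward the interior model and
a `degenerate` flag when the fitted amplitude is negligible.

Sessions enter tuning analyses only if the animal ran (speed > 1 cm/s) for
at least 25% of the stimulus period and reached 15 cm/s at least once.
Regional aggregation reports the Levene-significant fraction and the mean
Spearman rho of monotone-classified neurons with a 95% percentile
bootstrap CI over neurons (1000 resamples).

## 3. State-conditioned decoding

An **unregularised** 8-way multinomial logistic regression (lbfgs,
tolerance 10⁻⁶; implemented as `C=∞`, with a tiny-ridge refit only if the
solver fails to converge) is trained and tested separately on running and
stationary trials of a balanced trial matrix, over 10 random
class-stratified 50:50 train/test splits shared between the two state
decoders. Controls:

* **Within-class shuffling** — each neuron's responses are independently
  permuted across trials of the same (direction, state) cell. This
  preserves every single-neuron marginal exactly (the tests assert
  multiset equality) while destroying noise correlations.
* **Exclusions** — `running_positive` removes neurons classified as
  significantly positively speed-tuned; `reliability_top_k` removes the
  k% of neurons with the largest absolute reliability change between
  states. Sessions with fewer than 10 surviving neurons are excluded.

Across sessions, the paired running − stationary accuracy difference is
tested with a two-sided Wilcoxon signed-rank test. For ≤ 25 non-zero
differences the **exact** sign-flip null distribution is used, built by
convolution over doubled midranks (ties supported); the implementation is
verified against brute-force enumeration of all 2ⁿ sign assignments. At
least 6 paired sessions are required.

## 4. Reliability and grating metrics

**Reliability** of a stimuli × trials response matrix is the variance of
the per-stimulus mean responses divided by the variance of all responses
(population variances throughout, so with equal trial counts the statistic
lies in [0, 1]). It is 1 for noiseless stimulus-dependent responses, 0
when per-stimulus means are equal, and follows the law of total variance
in between: for two stimuli with means 0 and 1 (signal variance 0.25) and
unit trial noise it converges to 0.25/1.25 = 0.2. It is undefined (NaN)
for a constant matrix and invariant to affine transforms of the responses.

Per neuron, the package also reports the preferred direction (argmax of
the state-pooled mean), DSI = (R_pref − R_null)/(R_pref + R_null) with the
null direction orthogonal to preferred, a one-way ANOVA responsiveness p
across directions, percent state changes of preferred vs non-preferred
responses (stationary baseline), preference-sorted z-scored population
tuning curves per state with neuron-bootstrap CIs, and OLS with a Wald
t-test on the slope plus a 1000-resample bootstrap line envelope for
population-level regressions (e.g. decoding gap vs mean reliability
change).

## 5. LIF mechanism model

The membrane voltage obeys C_m dV/dt + g_l (V − E_l) = I_app, integrated
by Euler's method; a spike is emitted and V resets to E_l when V crosses
V_thresh. Gaussian noise is added to the voltage at every step.

| Parameter | Value | Note |
| --- | --- | --- |
| C_m | 490 pF | membrane capacitance |
| g_l | 16 nS | leak conductance (τ = C_m/g_l ≈ 30.6 ms) |
| E_l | −65 mV | leak reversal = reset |
| V_thresh | −49 mV | spike threshold |
| V_init | −70 mV | initial voltage |
| dt | 0.05 ms | Euler step |
| trial | 300 ms | per-stimulus trial |
| noise σ² | 19 / 36 mV² | in-vivo running / stationary pair |

Units close dimensionally: nS·mV = pA and pA·ms/pF = mV. The rheobase is
g_l(V_thresh − E_l) = 0.256 nA, and the noise-free interspike interval has
the closed form T = τ·ln[(I/g)/(I/g − (V_thresh − E_l))], which the
simulator matches within one Euler step per spike (acceptance-tested over
a 10-current grid).

Because a variance in mV² does not pin down a discretisation convention,
three per-step noise scalings are provided: `per_step` (the stated
variance injected every step; the literal reading and the default),
`per_ms` (scaled by dt), and `stationary` (scaled so the subthreshold
voltage's stationary variance equals the stated value). All three
reproduce the qualitative mechanism; the default was kept because the
headline ordering — at the in-vivo noise pair, the lower-noise condition
fires *less* but *more reliably* at every suprathreshold drive, and
subthreshold firing is purely noise-driven — holds under it.

Stimuli map to applied current through a Gaussian tuning curve over 15
stimulus indices (width 2 indices), each presented 10 times per run in
random order; reliability of the spike-count matrix uses the same
statistic as the imaging data.

## 6. Synthetic-session generator

The generator is the package's ground-truth instrument: every analysis is
validated against planted parameters.

* **Running bouts** — a two-state Markov chain per frame
  (p_start = 1/300, p_stop = 1/270 at 30 Hz → mean dwells of 10 s/9 s and
  roughly half the time running), per-bout target speeds uniform in
  8–25 cm/s with within-bout jitter, Gaussian-smoothed into ramps; pupil
  is an affine function of smoothed speed plus noise.
* **Speed tuning** — monotone-up/-down neurons add ±gain·speed
  (0.005 ΔF/F per cm/s), non-monotonic neurons a Gaussian bump (amplitude
  0.1, centre 6–14 cm/s, width 4 cm/s); untuned neurons add nothing.
* **Evoked responses** — von-Mises direction tuning (κ = 1.5, lognormal
  amplitudes, median 0.15) plus an untuned evoked offset (0.12), scaled
  by a per-trial multiplicative gain shared across neurons
  (sd 0.15) that induces realistic noise correlations.
* **State-dependent noise** — per-trial Gaussian noise whose sd is 0.25
  for stationary-like trials and, for a configurable fraction of neurons
  (default 50%), drops to 0.10 for running-like trials. This "reliability
  gap" changes no mean response, only trial-to-trial variability — exactly
  the mechanism the decoding scenario is designed to recover.
* **Scenarios** — `reliability_gap` (the headline), `null` (no state
  effect of any kind), and `suppression` (running halves the untuned
  evoked component, lowering mainly non-preferred responses — the
  activity-reduction motif of anterior areas).

The default tuning amplitudes are deliberately mild: speed-tuned responses
necessarily vary *across* running trials (bout speeds differ), which adds
running-specific response variance unrelated to the planted noise
mechanism. Amplitudes were chosen, before any test was frozen, so that
this mean-tuning variance is small relative to the planted noise change;
the residual decoding gap after the top-50% reliability exclusion then
fluctuates around zero instead of being consistently negative.

What the generator does **not** emulate: calcium-indicator dynamics are
off by default (an optional exponential kernel is provided), there is no
slow drift or photobleaching in ΔF/F, no eye movements, and the trial
noise is Gaussian rather than heavy-tailed. These omissions keep every
planted quantity analytically predictable — per-state reliability, for
instance, is tested against the exact variance decomposition of the model
with finite-trial corrections.

## 7. Determinism and problem sizes

All randomness flows from explicit integer seeds through a single fan-out
helper (`SeedSequence` keyed by stage names), so sessions, analyses, the
replay pipeline and the acceptance script are exactly reproducible; replay
reports are byte-identical across runs with the same seed.

Default problem sizes are the package's own choices, set to keep the full
test suite under two minutes and the acceptance script under one minute on
a single CPU: validation scenarios use 100-neuron sessions with 40
repetitions per direction (≈ 13 balanced trials per cell), calibration
uses 1000 white-noise neurons, and LIF grids use 8 drive levels × 10–15
runs. The session layout itself (8 × 75 repetitions) remains available
for full-scale runs.

## 8. Known limitations

* **The variance test is anticonservative under trial-correlated noise.**
  The permutation destroys the within-trial correlation structure of the
  activity trace, so any trial-level variability (which real neurons and
  the generator's per-trial noise both have) inflates the real curve's
  variance relative to permuted curves. On such data the test flags most
  neurons as `nonmonotonic` regardless of speed tuning; its 5%
  calibration holds only for temporally white activity, and the monotone
  classes (gated by Spearman on the binned curve) remain calibrated
  either way. Interpret the `nonmonotonic` fraction as "trial-to-trial
  variable", not "speed-tuned", on trial-structured data.
* **Unregularised multinomial regression is not unique** when neurons
  outnumber trials; accuracies are stable but coefficients (and therefore
  predictions after affine feature transforms) are not bit-reproducible
  across re-parameterisations. Decoding comparisons should rely on the
  shared-split accuracies, as the pipeline does.
* **Reliability is undefined** for constant response matrices and upward
  biased at very small trial counts; the balancing step guarantees equal
  counts but not large ones. The finite-trial expectation used in the
  tests quantifies this bias.
* The exact Wilcoxon implementation resolves ties by midranks over the
  true sign-flip distribution; p-values can differ slightly from
  large-sample or other tie conventions.
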