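# Methods

## The prediction problem

Freezing of gait (FOG) is treated as the terminal event of a short
deterioration phase (preFOG). The pipeline learns to recognize preFOG
from sliding windows of multi-IMU signals and converts window
predictions into alarms, so performance can be read both at the window
level (F1, Cohen's kappa) and at the episode level (hit rate,
false-positive rate, mean prediction time). Freeze-labeled data are
excluded everywhere: the classifier is a prefog-vs-normal binary model,
never a freeze detector.

## Synthetic gait generator

No agreed signal-level morphology exists for preFOG, and the underlying
clinical recordings are not available, so the generator plants a
*stand-in* deterioration whose strength is controlled by one knob:

- **Normal gait.** Per sensor, a phase process
  φ(t) = 2π ∫ f₀ (1 + j(t)) dt with step frequency f₀ = 1.8 Hz and
  white cadence jitter j(t) (sd 0.02) drives a sinusoid plus a 0.2×
  second harmonic; sensors get random phase offsets and amplitude
  scalings (0.8–1.2), channels get independent phases. White noise
  (sd 0.1) and sparse burst outliers (rate 0.001/sample, amplitude
  ±10× channel sd) are added.
- **preFOG ramp.** Over `prefog_ramp_s` (3 s) before each onset, gait
  amplitude decays linearly by `prefog_drift` and the cadence-jitter sd
  grows by 8×`prefog_drift`. Drift 0 produces *no* planted signal; the
  acceptance suite uses 0.6 for the signal cohort and 0 for the null
  cohort.
- **Freeze.** Gait amplitude drops to 30 % and a 3–8 Hz trembling
  component (three random tones, unit mean power, amplitude
  `fog_amplitude` = 2) is added, mirroring the elevated freeze-band
  power of real episodes.

The physical ramp length (3 s) is deliberately independent of the
preFOG *label* duration hyperparameter: the true preFOG extent is
unknown in practice, and the design sweep scans label durations against
a fixed underlying ramp. What passing tests show is that the pipeline
recovers a planted, smoothly parameterized deterioration under
patient-independent evaluation; they do not show that real preFOG looks
like amplitude decay plus jitter, nor that clinical hit rates would
match the synthetic ones.

## Cleaning and labeling

Order: percentile outlier replacement → high-pass detrending →
segmentation. Outliers are defined per channel over the whole
recording (strictly outside the [2.5, 97.5] percentile interval,
linear-interpolation percentiles) and replaced by the channel median of
the original series; the strict inequality keeps the cleaner idempotent
on clean data. Detrending is a zero-phase (forward–backward)
Butterworth high-pass, order 4, cutoff 0.3 Hz — below the slowest gait
content but high enough to remove drift and DC.

Candidate windows start at multiples of `step`; any window overlapping
a freeze by one sample or more is discarded (no leakage across the
onset). The label anchor is the window's **last** sample: prediction
is causal, so the label reflects the most recent instant the model
could have seen. preFOG zones `[onset − D, onset)` are clipped at the
recording start and keep their label there. All coordinates are
0-based, half-open, in samples (10 ms at 100 Hz).

## Feature bank

All 22 features use population (1/Ns) moments. The spectrum is the
one-sided DFT magnitude of the raw, untapered window, Nfft = Ns, DC bin
excluded — no taper or padding, and excluding DC prevents any
detrending residue from dominating the spectral means. Conventions
worth noting:

- F13 is mean/sd ("reciprocal coefficient of variation"); F14/F15 are
  *non-centered* standardized third/fourth moments, distinct from the
  central skewness (F08) and kurtosis (F09). Kurtoses are non-excess.
- The clearance factor (F16) is max|x| / (mean √|x|)² by default; a
  `strict_clearance` flag reproduces the crest-factor duplicate form
  instead.
- F21 (RMS frequency) includes the square root; F22 (variance of
  frequency) does not.
- The energy-operator series Δx wraps its endpoints
  (Δx(1) = x(1)² − x(2)x(Ns), Δx(Ns) = x(Ns)² − x(1)x(Ns−1)).
- Degenerate windows (zero spread or zero amplitude) map the affected
  ratio features to 0 and set a flag, keeping the matrix finite for
  forest training.

Standardization is z-scoring with mean/sd fitted on training rows only;
zero-spread columns pass through and are flagged. In cross-validation
the scaler is refitted inside every fold.

## Orthogonal design and effect analysis

The L16(4³) array is stored as its level-index matrix and instantiated
with the studied levels: window {128, 256, 400, 500}, step
{5, 10, 20, 30}, preFOG duration {150, 250, 500, 600} (samples).
`verify_orthogonality` checks the strength-2 property: each level 4×
per factor, and every ordered pair of levels of every factor pair with
equal frequency (exactly once for L16, four times for the 4³ full
factorial).

With one replicate the 16-run table cannot support a categorical
4-level ANOVA with interactions, so the default coding is numeric:
centered level values as covariates, plus a centered product term for
each requested two-factor interaction, fitted by OLS; with replicates a
type-II categorical ANOVA is used instead (`coding="auto"` decides by
residual df). Three-factor interactions are rejected by design.
Significance is reported as LogWorth = −log₁₀(p). A perfectly flat
response short-circuits to p = 1 (OLS would otherwise manufacture
~1e-19 coefficients with meaningless p-values). `select_best`
maximizes the per-level mean response (F1 by default) independently per
factor; ties (within 1e-9) resolve toward the cheaper, more causal
setting — smaller window, larger step, shorter preFOG duration.

## Classifier and window metrics

scikit-learn's RandomForestClassifier with defaults fixed at
(800, 0.1, 4, 4, 4); `max_features` is a fraction, giving
floor(0.1 × 924) = 92 candidates per split. Evaluation is
leave-one-patient-out; training folds with a single class are skipped
with a logged cause. F1 is the prefog-class score 2TP/(2TP+FN+FP);
kappa is Cohen's on the 2×2 window confusion; fold confusions are
pooled (micro) by default, macro averages are available. Top-K
selection ranks columns by mean impurity importance across the LOPO
folds (each forest sees only its training rows), re-evaluates each K,
and breaks ties toward higher kappa, then smaller K; importances are
also aggregated per base feature id (F01–F22) across channels for
reporting.

## Episode metrics

Maximal runs of prefog-predicted windows (optionally bridging up to g
non-prefog windows) form alarms spanning first-window start to
last-window end. Each alarm carries a *trigger*: the end of its first
prefog window — the earliest moment the alarm could causally be raised,
since the span start predates any observed data by a full window
length. (With long windows and short labels, e.g. a 5-s window and a
1.5-s label zone, the span start lies ~6.5 s before onset — outside any
horizon tied to the label durations — even though the prediction is
correct; the trigger is what a cueing device would act on.) An episode
is hit iff an alarm triggers in [onset − horizon, onset); prediction
time is measured from the earliest such trigger, so it always lies in
(0, horizon]. An alarm is false iff no onset follows within the
horizon of its trigger; the false-positive rate is per alarm, because
normal gait has no natural episode denominator. Alarms triggering
inside an ongoing freeze are ignored (neither hit nor false). Alarms
constructed directly, without window provenance, default their trigger
to the span start. The horizon defaults to
6 s — the largest studied preFOG label duration — and is configurable.
Significance of the pooled hit rate is assessed against a null built by
circularly shifting each patient's alarm train by an independent
uniform offset (100 permutations), which preserves alarm count and
spacing while breaking alignment with onsets.

## Fixture scale and numerical choices

The test and acceptance cohort is 6 patients × 50-s walks with two 5-s
freezes (onsets 14 s and 33 s), drift 0.6. The 14-s inter-freeze gaps
matter: every gap must exceed the largest window (5 s) plus the largest
preFOG label (6 s), otherwise some design runs have no normal windows
at all and their metrics are undefined. The 16-run sweep and the
episode evaluation use a 100-tree screening forest (other
hyperparameters from the optimized tuple); the library default stays at
800 trees. Per-stage seeds derive deterministically from one global
seed; artifacts are written at fixed precision (10 significant digits
for signals) so reruns reproduce files byte for byte. Row order into
the batched FFT can change last-bit rounding (SIMD lanes), so exact
reproducibility claims are per-run, and cross-ordering comparisons hold
to 1e-12 relative.

## Known limitations

- The preFOG morphology is an assumption of the generator, not a
  clinical finding; effect sizes, selected parameters and episode
  metrics on synthetic cohorts are structural demonstrations only. In
  particular, the selected windowing optimum on the synthetic cohort
  reflects the generator's 3-s ramp, not any property of patients.
- The numeric-coding interaction fit estimates a single linear×linear
  interaction component from 16 runs; a full categorical interaction
  needs replicates.
- No magnetometer channels, no biomechanical body model, no distinct
  regimes for turns or doorways; recordings are gap-free at a fixed
  rate.
- Class imbalance is left unweighted by default (a balanced-weights
  flag exists on RFParams).
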