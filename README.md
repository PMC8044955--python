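# fogcast

Predicting freezing of gait (FOG) before it happens, from body-worn
inertial sensors.

FOG is an episodic inability to start or continue walking in Parkinson's
disease. The premise of this package is that FOG is not sudden: in the
seconds before an episode there is a detectable deterioration of gait
(the *preFOG* phase), so a classifier trained to recognize preFOG
windows can raise an alarm early enough for a cueing intervention.
`fogcast` implements that pipeline end to end for multi-IMU recordings
(7 sensors × 3-axis accelerometer + 3-axis gyroscope at 100 Hz) and,
because clinical recordings of this kind are rarely shareable, ships a
synthetic-gait generator so every stage is testable and reproducible.

## What the pipeline does

1. **Simulate** (`fogcast.synth`): quasi-periodic gait at a step
   frequency f₀ (default 1.8 Hz) with white noise and sparse burst
   outliers; before each scheduled freeze, amplitude decays and cadence
   jitter grows linearly over a short ramp; during a freeze, the
   locomotor band collapses and a 3–8 Hz trembling oscillation appears.
2. **Clean & label** (`fogcast.preprocess`): per-channel replacement of
   samples outside the [2.5, 97.5] percentile interval by the channel
   median; zero-phase Butterworth high-pass detrending; sliding-window
   segmentation. Windows touching a freeze are discarded; a window is
   labeled `prefog` iff its last sample falls within `prefog_duration`
   samples before a FOG onset, else `normal`.
3. **Extract features** (`fogcast.features`): 22 statistics per channel
   per window — extrema, population moments, skewness/kurtosis, crest,
   impulse and clearance factors, the kurtosis of the Teager-style
   energy operator Δx(i) = x(i)² − x(i+1)x(i−1), and four spectral
   summaries (mean amplitude, center frequency f_C = Σf·X/ΣX, RMS
   frequency, variance of frequency about f_C). With 7 × 6 channels
   this gives the 924-column feature matrix, z-scored on training rows.
4. **Screen hyperparameters** (`fogcast.oed`): the three windowing
   hyperparameters (window size, step, preFOG duration; four levels
   each) are swept with a Taguchi L16(4³) orthogonal array — every
   pairwise level combination exactly once, 16 runs instead of the
   64-run full factorial. A linear model on the per-run F1/kappa
   responses yields main effects, a window×preFOG-duration interaction,
   and LogWorth = −log₁₀(p) significance; `select_best` picks the level
   combination maximizing the mean response.
5. **Classify** (`fogcast.model`): a random forest
   (n_estimators, max_features, max_depth, min_samples_split,
   min_samples_leaf) = (800, 0.1, 4, 4, 4) — so 924 × 0.1 = 92 candidate
   features per split — under leave-one-patient-out cross-validation,
   scored with the prefog-class F1 = 2TP/(2TP+FN+FP) and Cohen's kappa;
   optional top-K feature selection by impurity importance.
6. **Evaluate episodes** (`fogcast.evaluate`): runs of prefog-predicted
   windows merge into alarms, each triggering at the end of its first
   prefog window (the earliest causal alarm moment); an episode is
   *hit* when an alarm triggers within the horizon (default 6 s) before
   its onset, with prediction time = onset − first trigger; unconfirmed
   alarms are false alarms. Reported: hit rate, per-alarm false-positive rate, and mean
   prediction time (MPT), plus a circular-shift permutation null for
   the hit rate.

## Worked example

```python
from collections import Counter
from fogcast import (GaitSimParams, simulate_recording, replace_outliers,
                     highpass_detrend, segment_and_label, SegmentationParams,
                     extract_matrix, build_l16_4_3, default_factors,
                     verify_orthogonality)

params = GaitSimParams(prefog_drift=0.6, seed=7)
rec, ann = simulate_recording(params, 50.0, [(14.0, 5.0), (33.0, 5.0)])
print("samples:", rec.n_samples, "FOG events:", ann.fog_events)

clean = highpass_detrend(replace_outliers(rec))
ws = segment_and_label(clean, ann, SegmentationParams(500, 20, 250))
print("windows:", len(ws), dict(Counter(w.label for w in ws.windows)))

fm = extract_matrix(ws)
print("feature matrix:", fm.features.shape)

design = build_l16_4_3(default_factors())
print(design.runs.head(3).to_string(index=False))
print("balanced:", verify_orthogonality(design).passed)
```

prints

```
samples: 5000 FOG events: [(1400, 1900), (3300, 3800)]
windows: 128 {'normal': 102, 'prefog': 26}
feature matrix: (128, 924)
run_id  window_size  step  prefog_duration
   T01          128     5              150
   T02          128    10              250
   T03          128    20              500
balanced: True
```

i.e. a 50-s recording (5000 samples at 100 Hz) with two annotated
freezes at samples 1400 and 3300; 128 windows survive after removing
those overlapping a freeze, 26 of them in the 2.5-s preFOG zones; each
window yields the 924 features; and the 16-run orthogonal design passes
its balance checks.

The same workflow is available from the shell:

```sh
fogcast all --seed 7 --out artifacts/
```

which chains simulate → design → design sweep → effect analysis →
best-parameter selection → retraining → episode evaluation, writing
CSV/JSON artifacts with content-hash manifests.

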