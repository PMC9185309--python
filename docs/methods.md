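# Methods

`csecg` implements a complete heartbeat-classification pipeline for
single-lead ambulatory ECG under the AAMI five-class scheme (N, S, V, F,
Q), with a per-batch dynamic cost-sensitive loss as the treatment for the
extreme class imbalance of arrhythmia data. This note records the models,
the numerical choices, and what the synthetic test bed does and does not
establish.

## Signal model and preprocessing

The input is a sampled voltage trace (nominally modified limb lead II at
360 Hz) with per-beat annotations: an R-peak sample index and a MIT-BIH
beat symbol, mapped to its AAMI class by a fixed symbol table. Paced
records (102, 104, 107, 217 of the 48-record database) are excluded; the
remaining 44 records form the standard inter-patient split DS1/DS2 (22
training and 22 test records).

Denoising is a two-stage chain:

1. **Baseline wander** — a median filter with a 200 ms window (removes P
   waves and QRS complexes) cascaded with a 600 ms window (removes T
   waves) estimates the baseline, which is subtracted from the raw trace.
   Window lengths are `round(w·fs)` forced odd — an odd window yields an
   exact order statistic — giving 73 and 217 samples at 360 Hz. Edges use
   reflect padding, which avoids the step artefacts of zero padding.
   The estimator is only *approximately* idempotent: at 60–75 bpm the T
   wave spans 40–60 % of the 600 ms window, so re-applying the operator
   re-estimates a residual baseline of order 0.01 mV (a few percent of the
   corrected signal's RMS, ~1 % of the R amplitude). The tests assert this
   honest bound rather than exact idempotence.
2. **High-frequency noise** — a linear-phase FIR low-pass of order 12
   (13 taps, Hamming window, unity DC gain) cut off at 35 Hz. The constant
   group delay of 6 samples is compensated by reflect-padding and taking
   the centred valid part, so peak indices remain in raw-signal
   coordinates. An order-12 FIR at 360 Hz attenuates 50/60 Hz only mildly
   (it is not a notch); tests assert relative attenuation, not rejection.

## Segmentation

R peaks are detected with the Pan–Tompkins algorithm using its published
constants: 5–15 Hz band-pass (zero-phase second-order Butterworth),
five-point derivative, squaring, 150 ms moving-window integration, dual
adaptive signal/noise thresholds with a 200 ms refractory period, and the
360 ms T-wave discrimination rule (a candidate within 360 ms of the last
accepted peak is rejected if its maximum upslope is below half of the
previous peak's). Accepted integrator peaks are snapped to the extremum of
the band-passed signal within the preceding 225 ms. Search-back on missed
beats is not implemented; at the noise levels studied here the adaptive
thresholds recover ≥ 95 % of beats (measured, see the acceptance script).

The T point of a beat is the sample of maximum absolute amplitude in the
window from 80 ms after the R peak to min(400 ms, 70 % of the current RR
interval) — the standard T search window; absolute amplitude handles
inverted T waves. The classifier's input unit is **two consecutive T-to-T
intervals**: a beat whose R index falls in the interval (T[k−1], T[k]]
(boundary ties go to the following interval) contributes
`rescale(T[k−2]→T[k−1]) ++ rescale(T[k−1]→T[k])`, each interval linearly
resampled to 200 samples (endpoints preserved), for a 400-sample vector.
Beats without two preceding T points (the first beats of a record) are
dropped and counted. No amplitude normalisation is applied; an optional
z-scoring flag exists but defaults off.

## Network

A 1-D CNN on the 400-sample segment:

    conv(16, k=5) → maxpool(2,2) → transition(8,8,16) → conv(32, k=5)
    → transition(16,16,32) → conv(64, k=5) → global-average-pool
    → FC(64, dropout 0.75) → softmax(5)

Each **convolution block** is convolution (same padding) → batch
normalisation → ReLU → dropout (0.2 in the blocks; the 0.75 ceiling is
applied at the fully connected layer). Each **temporal transition module**
runs three parallel convolutions with kernels 1, 3 and 11 — short- and
long-range morphology at the same depth — each followed by batch norm and
ReLU, concatenated along the channel axis. The third kernel defaults to 11
(15 and 21 remain selectable). Setting `transition_filters=()` removes the
modules and yields the plain-CNN ablation baseline.

Training is plain SGD (initial learning rate 0.01) with L2 weight decay
0.003 on the convolution kernels. The network is implemented directly on
NumPy arrays with hand-written backpropagation (im2col convolutions,
standard batch-norm gradients, inverted dropout), float32 by default; a
float64 mode exists and is used by the finite-difference gradient test.
All randomness — initialisation, batch order, dropout masks — derives from
the single config seed, so runs are bit-reproducible. Evaluation-mode
forward passes are deterministic (dropout off, batch-norm running
statistics) and chunked at 256 segments to stay cache-resident.

The exact depth and filter counts of the published architecture are not
fully specified; the default above honours every stated element while
remaining trainable on one CPU, and everything is configurable. A slimmer
`ModelConfig.small()` (8/16/32 filters, pool 4, FC 32; ~12 k parameters)
is the default for the desk-scale protocols below.

## Cost-sensitive loss

For a mini-batch of M segments over C = 5 classes, the per-class
misclassification cost is

    φ_c = CW_c + HM_c

with two ingredients, recomputed for **every** batch:

* **Blended class weights.** Inverse-frequency balanced weights
  `w_c = n_total/(C·n_c)` are computed for the batch (CW_b) and the whole
  training set (CW_D) and blended by their quadratic mean,
  `CW_c = sqrt((CW_b,c² + CW_D,c²)/2)`, which lies between the two and
  leans toward the larger — a batch whose composition drifts from the
  dataset still gets a stable weight. For balanced data all weights are 1.
  The defining texts leave the weight formula itself open; the
  inverse-frequency reading is this package's documented choice (the
  standard cost-sensitive weighting, and the only direction that
  up-weights minorities). A class absent from a batch inherits CW_D so the
  blend is finite.
* **Performance term.** One-vs-rest false-positive and false-negative
  rates of the model's arg-max predictions on the current batch (from the
  same forward pass that produces the loss), combined per class by their
  harmonic mean `HM_c = 2/(FPR_c⁻¹ + FNR_c⁻¹)`, with ε = 1e−7 inside the
  reciprocals and the either-rate-zero case defined as 0 (the continuous
  limit: a clean side earns no penalty). FPR and FNR are per-class
  vectors, not batch scalars — φ must differ across classes to rebalance
  anything.

The batch loss is `mean_i φ[y_i]·(−log ŷ_i[y_i])` (natural log,
probabilities clamped at 1e−12). φ is a batch statistic: no gradient flows
through it, and it is not renormalised across the batch; an optional
`phi_max` cap exists and defaults to off.

## Evaluation

From a C×C confusion matrix (rows true, columns predicted), one-vs-rest
counts give per class: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
positive productivity TP/(TP+FP), accuracy (TP+TN)/total, reported in
percent. **Macro** is the unweighted mean over the five classes; a class
with no true and no predicted samples has undefined rates, reported as NaN
and excluded from the macro. **Aggregate** is the gross (micro) statistic
from the classwise-summed counts; published aggregate rows for this
method do not match any simple micro derivation, so the micro reading is
documented as this package's definition and only the per-class and macro
rows are asserted against the published tables. Internal math is full
precision; display rounds half-up to two decimals, matching the tables.

Protocols: **intra-patient** — beat-wise stratified 10-fold
cross-validation (the paradigm places every patient's beats in both
training and test, so stratification is over beats); per-fold confusion
matrices are pooled before computing metrics, which also scores classes
too rare to appear in every fold. **Inter-patient** — one model trained on
DS1 segments, evaluated once on DS2, with record-set disjointness asserted
before training. The loss comparison trains paired cost-sensitive and
cross-entropy arms with identical architecture, seed, schedule and batch
order per seed, and reports per-arm means and differences over ≥ 5 seeds,
including the minority-class (S∪V∪F) macro sensitivity the imbalance
treatment targets.

## Synthetic test bed

Each synthetic heartbeat is a sum of Gaussian waves (P, Q, R, S, T) with
class-conditional parameters: N canonical; S premature (preceding RR
shortened ×0.7) with a reduced P wave; V wide high-amplitude QRS, no P,
discordant T; F the N/V midpoint; Q randomised (3–6 waves with broad
uniform amplitudes/widths/offsets). Records add a baseline sinusoid
(0.10 mV at 0.25 Hz), a powerline sinusoid (0.02 mV at 60 Hz) and white
noise (0.01 mV), and emit analytic R/T fiducials plus MIT-BIH symbols, so
detection and segmentation are scored against exact ground truth.

The **imbalanced benchmark** draws ~5,000 training and ~2,000 test
segments with the database's class proportions
(≈ 0.895 : 0.028 : 0.070 : 0.008 : 0.00015; Q floor-clamped to 2 per
split), built directly as 400-sample two-interval segments (bypassing
detection), with distinct per-split "subject" morphology scalings
(amplitudes and widths perturbed ±5–15 % in opposite directions) to mimic
inter-patient shift. Benchmark training uses the small model for ≤ 10
epochs — sized so the full 5-seed paired comparison runs on one CPU in
about ten minutes.

What passing on this bed shows: the pipeline's operations are correct
(oracle-checked), the loss algebra is exact, and cost-sensitive training
moves minority sensitivity in the right direction under realistic
imbalance. What it does not show: performance on real ECG. Gaussian-wave
beats are far more separable than real inter-patient morphology, contain
no atrial-fibrillation rhythms, ectopic couplets, artefact bursts or
electrode noise, and the "subject" shift is a crude amplitude/width
scaling. Headline accuracies on the real database are reproduced here
only at the metric level, from the published confusion matrices.

## Known limitations

* No search-back in the peak detector; very low-SNR or bradycardic edge
  cases may drop beats.
* The T-point locator is amplitude-based; biphasic T waves resolve to the
  larger lobe.
* WFDB-native reading requires the optional `wfdb` package; the plain-text
  fixture layout is the supported test path.
* The aggregate metric row is this package's micro reading (see above).
* Single-lead only; no RR-interval features; no focal-loss arm beyond the
  configuration hook.
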