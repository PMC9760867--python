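# Methods

This note documents the models and procedures implemented in `ecgbeats`, the
choices made where the design was genuinely open, and what the synthetic
test harness does and does not establish.

## Beat segmentation

The segmentation pipeline is deliberately minimal — no filtering, no
denoising, no fiducial-point model beyond the R peak:

1. **Resample** the selected lead (channel 0 for multi-lead records) to a
   working rate of 125 Hz by Fourier (band-limited) resampling. Output
   length is `round(n·fs_out/fs_in)`.
2. **Window**: non-overlapping 10 s windows (1250 samples); a final partial
   window is discarded.
3. **Normalize** each window to [0, 1] by min–max scaling. A constant
   window maps to all zeros (and therefore yields no peaks). Because the
   maximum of a normalized window is exactly 1, the R-peak threshold "0.9 of
   the normalized maximum" is the absolute value 0.9.
4. **Detect R peaks** as local maxima — samples where the first difference
   changes sign from positive to negative, with flat runs carrying the sign
   of the last nonzero difference and plateaus reporting their first sample —
   at or above the threshold. Candidates closer than a 0.2 s refractory
   interval are pruned keeping the larger, which prevents double detections
   on jagged QRS complexes.
5. **Period**: T is the median of successive R-R intervals in the window
   (mean of the two central values for an even count). Windows with fewer
   than two peaks are skipped, since T is undefined there.
6. **Segment**: for each peak `p`, the half-open span `[p, p + round(1.2·T))`
   is cut and zero-padded to L = 187 samples; spans longer than L are
   truncated, and spans crossing the window end use the available samples.

L = 187 is forced by the network's shape arithmetic: three valid kernel-3
convolutions and a size-2 pool map 187 → 185 → 183 → 181 → 90, matching the
classifier's printed feature-map sizes. All indices are 0-based, spans
half-open, and the pipeline contains no randomness.

## Labeling

Annotations (native-rate sample index + MIT-BIH beat symbol) are mapped to
the five AAMI EC57 superclasses; non-beat symbols are ignored. Indices are
converted to 125 Hz coordinates by `round(i·125/fs)`. A segment takes the
class of the annotation nearest its detected R peak if that annotation lies
within 0.15 s; otherwise the segment is dropped. The 0.15 s gate is roughly
half a refractory period, small enough that a label can never jump across a
neighboring beat at plausible heart rates.

## Classifier

Layer stack (input: one beat segment, shape 187×1):

| layer | output | parameters |
|---|---|---|
| SeparableConv1D k=3, 32 filters | 185×32 | 67 |
| SeparableConv1D k=3, 64 filters | 183×64 | 2,208 |
| SeparableConv1D k=3, 128 filters | 181×128 | 8,512 |
| BatchNorm | 181×128 | 512 |
| MaxPool 2/2 | 90×128 | 0 |
| BiLSTM 128 u/dir, final state | 256 | 263,168 |
| Flatten, Dropout 0.5 | 256 | 0 |
| Dense 512 | 512 | 131,584 |
| BatchNorm | 512 | 2,048 |
| Dense 5, softmax | 5 | 2,565 |

Totals: 410,664 parameters, of which 1,280 (the two batch-norm layers'
moving mean/variance) are non-trainable. A separable convolution has
`k·c_in` depthwise weights (no bias), `c_in·c_out` pointwise weights and
`c_out` biases; the bidirectional LSTM has `2·4·(u·(u+d)+u)` weights. The
closed-form calculator (`parameter_table`) and the built network are
required to agree layer by layer; this is asserted at build time.

All convolutions use valid padding, so each kernel-3 layer shortens the
sequence by two samples (185, 183, 181) and pooling halves it to 90. This
length arithmetic, together with the parameter counts above, is what pins
the input length to exactly 187.

The network is implemented in numpy (`ecgbeats.nn`) with explicit
forward/backward passes for every layer and Adam/RMSProp optimizers.
Analytic gradients are checked against central differences through the full
stack in the test suite. Numerical details:

* weights are Glorot-uniform initialised from a user seed; LSTM forget-gate
  biases start at 1;
* batch-norm uses epsilon 1e-3 and moving-average momentum 0.9 — chosen so
  the inference statistics converge within the few hundred gradient steps a
  typical run of this package performs (with momentum 0.99 the moving
  statistics would still be dominated by their initial values after tens of
  epochs on desk-scale data, making training-mode and inference-mode
  predictions diverge grossly);
* probabilities inside the loss are clipped at 1e-7 before the logarithm;
* the LSTM returns only the final step's concatenated state (256 values),
  matching the printed flatten size;
* dropout is inverted (scaling by 1/(1−rate) at train time);
* after training, batch-norm inference statistics are recalibrated: the
  moving moments are replaced by exact full-training-set moments computed
  with the final weights (one extra forward pass, done at the end of each
  fold and of final retraining). The exponential averages accumulated
  during training lag the weights and are noisy at small batch counts,
  which otherwise produces a large train/inference discrepancy at desk
  scale.

## Imbalance handling: the weighted loss

With `counts` the per-class beat counts of the training split,

    w_c = n_samples / (n_classes · count_c)

and the loss is the mean over samples of `−w_{y_i}·log p_i(y_i)`. Two exact
invariants are tested: balanced counts give all-ones weights, and
`Σ_c w_c·count_c = n_samples`. A class absent from the training split makes
its weight undefined; this raises an error rather than silently producing
infinities (stratified folds prevent it in practice). Weights are computed
from each fold's training split only, never from validation data.

## Training protocol

* Stratified k-fold assignment (default k = 10, seeded shuffle): folds
  partition the data with sizes differing by at most one and per-fold class
  proportions within one sample of the global ones. Stratification matters
  here because an unstratified fold can lack the rarest class entirely,
  leaving the weighted validation loss undefined.
* Each fold trains a freshly initialized network for the full epoch budget
  (default 100), batch size 128, Adam with initial learning rate 0.001
  (the optimizer's conventional default). The learning rate halves when the
  monitored loss has not improved for five consecutive epochs; the counter
  resets on improvement and after each halving. During cross-validation the
  monitor watches validation loss; during final retraining, training loss
  (no validation set exists then).
* The optimal epoch is the rounded mean of the per-fold epochs of minimum
  validation loss. The final model is re-initialized and trained on the
  full training set for exactly that many epochs. Test data is never seen
  during training, and the CLI refuses to evaluate a test-marked dataset a
  second time without `--force`.

## Evaluation

Per class, one-vs-rest: Acc = (TP+TN)/total, Sen = TP/(TP+FN),
Spe = TN/(TN+FP), PPV = TP/(TP+FP), F1 = 2·PPV·Sen/(PPV+Sen), reported as
percentages to two decimals; macro averages are unweighted means over the
five classes. A ratio with zero denominator is reported as 0 and flagged —
the degenerate case does not arise in realistic evaluations but does in
tests. The implementation is validated against a brute-force counter and
against scikit-learn's precision/recall on random inputs.

## Synthetic generator

Each beat is a sum of analytic bumps `a·exp(−|t−c|/σ)^ρ` (ρ = 2 except the
flat-topped paced beat, ρ = 4), concatenated at the configured heart rate
(default 75 bpm) with uniform R-R jitter (default ±8%), then overlaid with
0.3 Hz sinusoidal baseline wander (amplitude 0.05 of the QRS height), 50 Hz
powerline interference (0.02) and white noise (σ = 0.02). Class morphologies:
N has P-QRS-T; S lacks the P wave, has a narrow QRS and a 0.7× shortened
interval (premature coupling); V is a wide, slightly taller QRS with a
discordant T and no P; F is the component-wise average of N and V; Q is a
broad flat-topped pulse. QRS amplitudes deliberately stay within ~10% of
each other across classes: the detector thresholds at 0.9 of the per-window
maximum, so a much taller class would mask its neighbors' R peaks — a known
weakness of the threshold rule itself, not of the generator.

Default class proportions (0.828, 0.025, 0.066, 0.007, 0.074) mirror the
heavily imbalanced training distribution of the MIT-BIH-derived beat corpus
this pipeline targets (majority N ≈ 83%, rarest F ≈ 0.7%).

Annotations mark the exact QRS maximum of each generated beat, so detector
recall and precision can be scored exactly. On noise-free records the
detector recovers ≥ 99% of beats within ±2 samples at 125 Hz with ≥ 99%
precision; losses are window-edge beats and the discarded partial final
window. With the default noise mix the yield drops to roughly 75–80% —
the expected behavior of a fixed 0.9 amplitude threshold applied without
any filtering, and the reason segment counts always trail raw beat
tallies in this kind of pipeline.

**What the generator does not emulate:** real QRS morphology variation
within a class, pathological rhythm context (bigeminy, runs), electrode
artifacts, lead differences, or annotation noise. Passing tests therefore
demonstrate the correctness of the pipeline's mechanics and the qualitative
behavior of the weighted loss, not clinical-grade performance on real ECGs.

## Desk-scale study sizes

The test suite reproduces the weighted-loss effect at desk scale: five
paired seeds, each a ~5,000-segment synthetic dataset with ~100:1
majority:minority imbalance, 2-fold cross-validation, 10 epochs, on a
reduced-width spec (8/8/16 conv filters, 8 LSTM units, dense 32, optimizer
defaults) that preserves the architecture's shape while fitting a CPU
budget. In at least 4 of 5 paired seeds the class-weighted loss yields
strictly higher minority-class (F) recall and F1 than the unweighted loss.

The effect is regime-dependent, and the desk-scale setup deliberately sits
in the regime where it matters. Within a 10-epoch budget the reduced-width
model trained without weights is essentially minority-blind (F recall in
the single digits on most seeds) and weighting recovers it, lifting both
recall and F1 — the direction the method claims. With a wider desk model
and a larger learning rate the baseline already learns the minority class
from its ~50 examples, because the synthetic morphologies are cleanly
separable, and the two losses converge to similar F1; real ECGs, with
within-class variability the generator does not emulate, keep the
unweighted baseline minority-poor at full scale. Absolute full-scale
metrics (macro F1 ≈ 92% on MIT-BIH) require the real database and
~100-epoch × 10-fold training and are explicitly not claimed by the
desk-scale suite.

## Known limitations

* The 0.9 amplitude threshold makes detection sensitive to within-window
  amplitude spread; real records with large QRS variation will lose beats.
* Beats whose QRS falls within a couple of samples of a window boundary are
  undetectable by construction.
* The numpy engine is single-threaded per matmul and intended for
  correctness and desk-scale experiments, not large-scale training.
* WFDB support covers single-segment format-16 records with text
  annotations — sufficient for round-tripping this package's own output;
  arbitrary PhysioNet headers are out of scope.
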