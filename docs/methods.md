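# Methods

## Problem

Myoelectric pattern recognition (MPR) drives prostheses and gesture
interfaces by classifying motion intent from surface EMG. Classifiers
trained on a closed set of target gestures necessarily assign *every* probe
to some trained class, so untrained ("novel") motions — office activities
such as mouse use, writing and typing are the canonical offenders — leak
into the command stream as spurious gestures. This package implements an
open-set recognition pipeline for high-density sEMG (HD-sEMG): classify the
seven target tasks, and reject everything else.

## Pipeline

1. **Windowing and gating.** Recordings (96 monopolar channels on a 12 x 8
   grid, 1 kHz) are cut into overlapping windows of 250 ms with a 150 ms
   increment, giving a decision rate of 6.67 Hz. Quiescent windows are
   removed by an amplitude gate: per channel, mean + 3 SD of the rectified
   baseline signal, averaged over all channels; a window survives when its
   mean rectified amplitude over all channels and samples exceeds that
   level. Which exact statistic the convention intends is ambiguous
   ("rectified mean per channel, then averaged" vs. an RMS-envelope
   variant); the rectified-channel-then-average reading is the common
   HD-sEMG practice and is the one implemented.
2. **Feature images.** Each surviving window becomes a 12 x 8 x 3 array of
   per-electrode mean absolute value (MAV), waveform length (WL) and root
   mean square (RMS). Target-task samples are split 64 / 16 / 20 into
   train / validation / test, stratified per class with largest-remainder
   rounding so totals are exact.
3. **CNN classifier.** Two 3 x 3 convolutional layers with 32 filters each
   (ReLU; zero "same" padding so the 12 x 8 extent is preserved — with
   valid padding two 3 x 3 convolutions would discard the outermost
   electrode rings), then dense 1024 -> dense 512 -> dense M=7 with softmax.
   Dropout (drop probability 0.8) follows the two wide dense blocks.
   Training: mean cross-entropy (natural log), mini-batch AdaDelta
   (rho = 0.95, eps = 1e-6) with learning-rate multiplier 0.05, batch 16,
   100 epochs. The block-3 post-ReLU output is the 512-long embedding
   consumed by the novelty detectors; it is nonnegative by construction.
4. **Per-task autoencoders.** For each target task an autoencoder
   512 -> 256 -> 64 -> 256 -> 512 is trained on that task's *training*
   embeddings only (MSE, SGD, batch 16, lr 0.1 for 600 epochs then 0.01 for
   300). At test time the anomaly score of a probe under task k is the
   Bray-Curtis distance between embedding and reconstruction,
   E = sum|x - x^| / sum(x + x^), which lies in [0, 1] for nonnegative data.
5. **Threshold calibration.** A single recall factor r (default 0.85) is
   shared by all tasks: the threshold for task k is the ceil(r * n_k)-th
   smallest score of task k's own validation samples, so the achieved
   calibration acceptance is the smallest order statistic >= r. Acceptance
   is inclusive (score <= threshold); r = 0 accepts nothing, r = 1 accepts
   every calibration sample.
6. **Decision rule.** Default `any_accept`: a probe is accepted if *any*
   task's autoencoder fits it within that task's threshold; accepted probes
   take the CNN's argmax label, everything else returns NOVEL. The stricter
   `predicted_class` rule (accept only if the CNN-predicted task's own
   autoencoder fits) is available behind a flag; the two differ exactly on
   probes fitted only by a non-predicted task's autoencoder.

## Baselines

* **LDA** — the classic closed-set pipeline: per channel MAV, WL, zero
  crossings and slope-sign changes (384-long vector for 96 channels),
  linear discriminant analysis (eigen solver, shrinkage 1e-3 for the
  384-dim within-class covariance). ZC/SSC use a deadzone of 0.01 x the
  per-channel training SD; the feature definitions carry no canonical
  deadzone, so it is exposed in config.
* **LDA-MD** — the same classifier cascaded with Mahalanobis-distance
  rejection: probes are projected into the discriminant space (rank <= 6),
  and the anomaly score is the distance to the *predicted* class centroid
  under the pooled projected within-class covariance (an all-classes-minimum
  variant exists behind a flag; whether the classical cascade pools or uses
  class-specific covariance is not settled — pooled is the default here).
  Thresholds come from the same recall-factor calibration.

## Evaluation conventions

* **ROC** is rejection-stage only: positives are target test windows, TPR(r)
  is the fraction of target windows *accepted* at recall factor r, FPR(r)
  the fraction of novel windows accepted. Whether an accepted target window
  is also correctly classified is deliberately not part of the ROC — that is
  measured by the per-motion accuracy. The sweep recalibrates per-task
  thresholds on a 101-point recall grid and adds the degenerate accept-none
  (0,0) and accept-all (1,1) endpoints; AUC is the trapezoid rule over
  FPR-sorted points with ties resolved to the maximum TPR.
* **Per-motion accuracy**: a target window is correct iff accepted and
  labelled with its own task; a novel window is correct iff rejected (all
  six novel tasks share the single NOVEL label). The confusion matrix is
  13 true tasks x (7 predicted tasks + NOVEL); per-motion accuracies derived
  from it must equal the directly computed ones (asserted at run time).

## Synthetic benchmark

No public HD-sEMG corpus matches this recording protocol, so the package
ships a seeded generator that reproduces the statistical structure the
pipeline consumes, per subject:

* **Carrier**: Gaussian white noise through an order-4 Butterworth 20-500 Hz
  band-pass (the acquisition hardware's analog passband), independently per
  channel, amplitude-modulated by a spatial activation envelope.
* **Activation maps**: sums of Gaussian bumps on the grid; each isometric
  task has two bumps (one per muscle-group half of the stacked arrays).
  One synthetic subject = one draw of per-task bump centres (SD 0.3
  electrode pitches around the canonical layout). The pinch task (N1) sits
  between the wrist-flexion and hand-close maps — similar to trained
  patterns but resolvable — while radial/ulnar deviation (N2/N3) occupy
  distinct grid corners.
* **Within-class variability** is deliberately rich, because an open-set
  benchmark whose classes are trivially separable exercises nothing: every
  rejection method, linear or not, scores 100% on it. Three nuisance layers
  make the 7-class problem genuinely hard (the linear LDA baseline lands
  around 95-97% target accuracy, the operating regime the comparison is
  about): (a) per-repetition drift of activation centres (SD 1.0 electrode
  pitch — posture/electrode micro-shift) and repetition gains ~ U(0.6, 1.4)
  (force-level fluctuation); (b) a smooth low-amplitude co-contraction
  background (two very wide Gaussian bumps, peak gain 0.25, redrawn per
  repetition); (c) intra-repetition nonstationarity — centres, gains and the
  background are redrawn at 0.5-s knots and the envelope linearly
  interpolated between them, so no two analysis windows see an identical
  spatial configuration. Without (c), the sample-level 64/16/20 split lets
  every model partially memorize the finite set of per-repetition
  configurations shared by sibling windows, and open-set behaviour collapses
  to memorization checks.
* **Protocol**: per subject one quiescent baseline (20 s), 10 repetitions of
  5-s isometric contractions for each of the 7 target and 3 static-novel
  tasks, and ~60 s of continuous recording per dynamic novel task.
* **Dynamic novel tasks** switch every 0.5-2 s between superpositions of one
  trained pattern at in-manifold amplitude (weight ~ U(0.6, 1.4), the same
  range as repetition gain jitter; wrist pronation's map among the
  candidates) and a task-specific untrained component (weight
  ~ U(0.05, 0.75)) whose bumps sit in grid regions quiet in every trained
  task. A window is therefore a trained gesture performed simultaneously
  with variable extra activity — sometimes barely there, sometimes dominant
  — which is exactly the regime where a per-class Gaussian gate in the
  discriminant space degrades while the nonlinear embedding detector does
  not.
* **Amplitudes**: baseline noise floor 0.02 versus task gains ~1 (arbitrary
  units). The source protocol does not characterize its amplitude
  distributions, so SNR and variability settings are free config
  parameters; they are claims about the simulator, not about any real
  recording.

What the generator does *not* model: motor-unit action potentials,
electrode-shift sessions, limb-position effects, fatigue, inter-channel
noise correlation. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that its qualitative behaviour (closed-set
leakage, rejection orderings, score separation) emerges under the assumed
spatial-statistical structure — not that the numerical accuracies transfer
to physiological recordings.

## Numerical choices

* All network code is float32 NumPy, single-threaded, with every RNG stream
  derived from one master seed (SeedSequence spawning); runs are
  bit-reproducible.
* Weight init: He-style uniform (+/- sqrt(6/fan_in)); autoencoder biases
  start at 0.1 to keep rectified units initially alive.
* The autoencoder output layer is trained *linear* and its reconstruction
  clamped at zero when scoring. A rectified regression output under plain
  SGD suffers irrecoverably dead output units (a dead unit's coordinate
  reconstructs to 0 forever, inflating every score); the linear-output /
  clamped-scoring combination preserves the nonnegativity the Bray-Curtis
  denominator needs without that pathology.
* Conditioning: feature images are divided by per-feature-type (MAV/WL/RMS)
  training means before the CNN — WL is two orders of magnitude larger than
  MAV/RMS — and then each image by its own mean value, so the network sees
  contraction-level-invariant spatial patterns (`per_image_norm`, on by
  default). Embeddings are divided by one scalar (the RMS of training
  embedding values) before autoencoder training, with the global gradient
  norm clipped at 5 as a divergence guard for the early large-learning-rate
  steps. All divisors preserve nonnegativity and are stored with the
  models; Bray-Curtis is invariant to a common scaling of probe and
  reconstruction, so scoring is unaffected.
* Degenerate guards: an all-zero embedding/reconstruction pair scores 0
  (perfect reconstruction of nothing); cross-entropy clips probabilities at
  1e-12; the projected covariance carries a 1e-9 ridge; non-finite training
  loss aborts with a stage-tagged error.
* Dropout "rate 0.8" is read as drop probability (the Keras convention); a
  keep-probability reading is available via `dropout_is_keep_prob`.
* Dense-block widths not externally pinned (block 2 = 1024; autoencoder
  256/128/256) are configurable defaults; the 128-wide bottleneck measured
  strictly better than 64 on both AUC and novelty rejection at equal recall
  on the packaged benchmark.

## Problem sizes

Full-scale training on the default protocol yields ~2240 target and ~1700
novel windows per subject. The bundled test suite and the acceptance script
evaluate one synthetic subject at the full default training schedules
(100-epoch CNN, 600+300-epoch autoencoders) — per-subject models match the
study design, and one subject is one independent draw of the task layout;
the generator's default remains 3 subjects for multi-subject summaries.
Unit tests use reduced widths/epochs where only mechanics are under test.

## Known limitations

* The recall-factor sweep assumes all task thresholds move together; a
  per-task sweep or a shared multiplicative scale would trace different ROC
  curves.
* Accepted-but-misclassified target windows count against per-motion
  accuracy but not against the rejection-stage ROC; comparisons with
  closed-set accuracy figures must keep the two conventions apart.
* LDA-MD scores only the predicted class by default; probes near a decision
  boundary can be rejected even when another class would accept them.
* The synthetic benchmark's difficulty is controlled by construction;
  absolute accuracies on it are regression anchors, not performance claims.
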