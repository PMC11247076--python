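# Methods

`arousalkit` implements an automatic sleep-arousal detector for overnight
polysomnography (PSG) and the evaluation framework needed to judge whether
such a detector is clinically usable: event-level scoring, arousal-index
error, and a group-bias analysis across patient categories.

## Problem setting

An arousal is an abrupt shift in EEG frequency lasting at least 3 s, with
at least 10 s of preceding sleep; in practice events longer than 15 s are
scored as wake, so annotated arousals live in the 3–15 s range.  During
REM sleep (stage R) scoring additionally requires a concurrent rise in
chin-EMG tone.  The clinical summary statistic is the arousal index (ArI):
arousals per hour of sleep, where total sleep time (TST) is the non-wake
portion of the 30-s-epoch hypnogram.  The detector's clinical impact on a
recording is summarized by the **ArI error**, the absolute difference
between the predicted and the manually scored ArI.

## Signal chain

Three channels — one EEG, one EOG, one chin EMG — feed the model at 50 Hz.

1. **Antialias resampling.**  A windowed-sinc (Kaiser, 60 dB stopband)
   FIR low-pass with cutoff at the output Nyquist (25 Hz, −6 dB) and a
   transition band of 20 % of the output Nyquist is applied polyphase; the
   linear-phase delay is compensated, so filtering is effectively zero
   phase and event onsets are not displaced — important because event
   matching is by interval overlap.
2. **Moving normalization.**  Each channel is normalized by removing the
   mean and dividing by the RMS of the mean-removed samples over an
   18-minute (1080 s) *centered* window, truncated at the record edges,
   with an ε = 1e−8 guard so constant stretches map to zero instead of
   dividing by zero.  RMS is taken over the mean-removed window (the
   z-score-like convention); whether the raw-window RMS was intended is
   ambiguous in the sources this follows, and the mean-removed form was
   chosen as the standard contract.
3. **Label track.**  Annotated events are extended by 2 s before onset
   and 10 s after offset (autonomic responses surround the scored EEG
   shift), clipped to the record, merged where extensions overlap (a
   binary track cannot represent overlap), and rasterized at 50 Hz with
   half-open intervals: sample *t* is positive iff *t*/fs lies inside an
   extended event.

## Model

A 1-D U-net maps the 3×T input to a length-T arousal-probability track.
With `depth` encoder levels there are `2·depth` double-convolution blocks
(the reference configuration, depth 4, has eight).  Every convolution is
stride-1, same-padded, kernel 21 samples (0.42 s at 50 Hz).  Encoder
levels end in max-pooling by `pool_factor` (default 4); decoder levels
start with nearest-neighbour upsampling and concatenation of the matching
encoder skip.  Filter counts start at `base_filters` and double per level
(capped at 256).  A final 1×1 convolution and sigmoid produce the track,
so output length always equals input length; inputs must be divisible by
`pool_factor^depth`, which the chunked predictor guarantees by padding.

The network is implemented directly on NumPy primitives: im2col
convolutions executed as single GEMMs, with hand-derived backward passes
verified against central differences in the test suite.

Numerical choices:

* **Leaky rectifier (slope 0.01)** instead of a hard ReLU.  At the upper
  end of the cyclic learning rate the small network otherwise suffers
  irreversible dying-ReLU collapse (early-layer gradients exactly zero,
  constant output); the leaky slope keeps every unit trainable.
* **He initialization** of weights, zero biases, seeded; two builds from
  one seed are bit-identical.
* **Inference stitching**: full nights are predicted in chunks of 4096
  samples (~82 s) with 50 % overlap, keeping each chunk's central half
  (outer chunks also keep their edges), so every output sample is far
  from a zero-padded boundary.

## Training

* **Loss/optimizer**: binary cross entropy on logits, Adam.
* **Learning rate**: triangular cycle between 0.003 and 0.00075 with a
  four-epoch half-period (high → low → high over eight epochs).  An LR
  range-test utility probes a grid with short fresh-model runs and
  suggests bounds (steepest-descent LR, loss-minimum LR).
* **Augmentation**: per iteration, one channel is drawn uniformly per
  role (montage regularization) and each channel row is scaled by an
  independent factor ~ U[0.8, 1.3]; an additive-noise variant is exposed
  by configuration.
* **Splitting**: participant-wise — all recordings of a patient share a
  split; 80/20 train/validation among non-test patients; leakage is
  asserted every run.
* **Early stopping**: validation sample-AUPRC at 50 Hz; training stops
  after 15 epochs (configurable) without improvement and the best
  checkpoint is restored.
* **Class imbalance**: batches are random fixed-length chunks (4096
  samples); half of the draws are forced to contain at least one positive
  sample.  A floor of 25 optimizer updates per epoch keeps "epoch"
  meaningful on small cohorts.

## Event conversion

The 50 Hz track is averaged into 1 s segments (trailing partial segments
average their actual samples), binarized at a threshold, positive runs
separated by gaps ≤ 3 s (patience, inclusive comparison) are fused, and
events shorter than 15 s are dropped — consistent with detection on
extended labels, where a minimal 3 s arousal carries a 15 s label.  When
detection runs on raw labels the AASM floor of 3 s applies instead
(`PostprocessConfig.for_raw_labels`).  The threshold is chosen by
maximizing micro event F1 on a validation set over a 0.05…0.95 grid
(step 0.05), ties breaking toward the lower (more sensitive) threshold.

## Evaluation

* **Sample AUPRC** of the probability track against the binary label
  track (step-wise integration over all thresholds; constant scores give
  the prevalence).
* **Event matching** by nonempty overlap of half-open intervals, with
  asymmetric multi-overlap rules: *k* predictions over one manual event →
  1 TP and (k−1) FN; one prediction over *k* manual events → k TP and
  (k−1) FP.  The two-fold cases are the published convention; the
  generalization to k > 2 is this package's extrapolation and is
  documented as such.  Unmatched predictions are FP, unmatched manual
  events FN.
* **Micro F1**: confusion counts are summed over records before the
  ratio, so long recordings weigh more than short ones.
* **ArI error** per record, aggregated as mean ± SD and median (IQR),
  plus the Pearson correlation between predicted and annotated ArI.
  A correlation over records with zero variance is reported as missing,
  not coerced to 1.

## Bias analysis

Per-record ArI errors are grouped by metadata (sex, decade age bins
18–29 … 80+, and the seven diagnosis categories: SRBD, SRBD-Therapy,
SRMD, Insomnia, Hypersomnia, Parasomnia, NormalFinding; all but
SRBD-Therapy are non-exclusive).  The analysis runs Shapiro–Wilk per
group, a Kruskal–Wallis omnibus, Dunn's post-hoc z-tests on joint ranks
with tie correction and Bonferroni adjustment (never below the raw p,
capped at 1), and classical pooled-SD Cohen's d of each group against the
NormalFinding reference, binned none/small/moderate/large at
0.2/0.5/0.8.  Groups under n = 3 are excluded with a warning.

## Synthetic data

The generator emulates the statistical structure the pipeline needs, not
sleep physiology:

* hypnograms from a semi-Markov cycle model (initial wake, N1→N2→N3→N2→R
  cycles with N3 fading and R growing across the night, occasional
  awakenings);
* EEG as 1/f colored noise with a stage amplitude envelope (deep sleep
  larger), EOG as slow noise (amplified in R), EMG as white noise whose
  tone falls from wake to REM atonia;
* arousals as additive band-limited 12–20 Hz bursts (gain 2× the local
  envelope, 0.5 s cosine tapers) from a renewal process on sleep time:
  spacing = 10 s minimum gap + duration + Exp(mean) with the exponential
  mean set so the long-run rate equals the configured ArI (default 25/h,
  a plausible clinical average); durations uniform on 3–15 s; stage-R
  arousals additionally multiply the EMG by 3;
* metadata with clinical-looking marginals (SRBD 73 %, SRMD 17 %,
  Insomnia 16 %, Parasomnia 13 %, Hypersomnia 5 %, therapy on 40 % of
  SRBD nights, NormalFinding when nothing else is drawn).

A rate that cannot respect the 10 s gap constraint raises a configuration
error.  `simulate_predictions` emulates an imperfect detector (configurable
miss probability and spurious-event rate) so evaluation and bias fixtures
do not require training.

What passing tests on this data do **not** show: robustness to artifacts,
electrode failures, spindles/K-complexes mimicking arousals, or scorer
disagreement — the burst signature is deliberately clean and learnable so
the end-to-end mechanics can be verified in minutes on one CPU.

## Problem sizes used by the test suite and acceptance script

The learning smoke experiment uses 40 records of 10 minutes (30 train /
10 validation), target ArI 15/h (extended-label prevalence ≈ 0.08, under
the 0.10 design cap), a depth-3 / 8-filter / k = 21 U-net, batch 8, at
most 15 epochs with patience 5.  ArI recovery uses 100 eight-hour
event/hypnogram draws at 25/h.  Effect-size calibration uses n = 10⁴
samples for the unit-shift Cohen's d and 100 seeded replicates of
three-group null draws for the omnibus retention rate.  These sizes are
the package's desk-scale defaults; all are configurable.

## Known limitations

* The EDF writer stores 16-bit samples; signal round-trips are exact only
  to the per-channel quantization step ((max−min)/65535).
* The multi-overlap matching rules beyond two-fold are an extrapolation
  (see above).
* Whether predicted events during scored wake should be removed before
  ArI computation is left as a configuration decision (default: keep),
  since the convention is ambiguous; the synthetic truth never places
  events in wake.
* The NumPy U-net trains desk-scale problems in minutes but is not meant
  for thousand-night cohorts; the architecture and training loop are,
  however, faithful at any scale.
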