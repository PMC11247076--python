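# arousalkit

Automatic detection of sleep arousals in overnight polysomnography (PSG),
with the event-level and clinically oriented evaluation needed to judge
whether a detector is usable in a sleep laboratory.

Arousals — abrupt EEG frequency shifts of 3–15 s with at least 10 s of
preceding sleep, requiring a chin-EMG rise during REM — are scored
manually by experts today, which is slow and rater-dependent. The summary
statistic reported to clinicians is the arousal index (ArI): arousals per
hour of sleep. `arousalkit` is aimed at researchers and engineers building
or validating automated arousal scoring: it provides the full chain from
raw multichannel signals to detected events and report-level statistics,
plus a synthetic-PSG generator so everything is testable without any
clinical data.

## Method

* **Preprocessing** — one EEG, one EOG, one chin-EMG channel are low-pass
  filtered with a zero-phase FIR, downsampled to 50 Hz, and normalized by
  the mean and RMS over an 18-min moving window. Annotated arousals are
  extended by −2 s/+10 s and rasterized into a 50 Hz binary label track.
* **Model** — a 1-D U-net (eight double-convolution blocks at reference
  depth, kernel *k* = 21, length-preserving padding) maps the 3×T input
  to a per-sample arousal probability p(t) ∈ [0, 1] at 50 Hz. Implemented
  in pure NumPy with exact hand-derived gradients.
* **Training** — binary cross entropy, Adam, triangular cyclic learning
  rate between 3·10⁻³ and 7.5·10⁻⁴ every four epochs, random per-role
  channel choice and amplitude-factor augmentation (U[0.8, 1.3]),
  participant-wise 80/20 splitting, early stopping on validation AUPRC.
* **Event conversion** — p(t) is averaged into 1 s segments, thresholded,
  positive runs fused across gaps ≤ 3 s, events shorter than 15 s
  dropped; the threshold maximizes micro event F1 on validation data.
* **Evaluation** — sample AUPRC; overlap-based event matching (two
  predictions on one manual event → 1 TP + 1 FN; one prediction spanning
  two manual events → 2 TP + 1 FP); micro F1 = 2ΣTP/(2ΣTP+ΣFP+ΣFN) over
  record-summed counts; ArI error |ArI_pred − ArI_true| per record with
  mean/median/IQR and Pearson r.
* **Bias analysis** — ArI error compared across sex, age-decade, and
  diagnosis groups (SRBD, SRMD, insomnia, hypersomnia, parasomnia,
  treated SRBD, normal findings): Shapiro–Wilk, Kruskal–Wallis, Dunn
  post-hoc with Bonferroni, and Cohen's d against the normal-findings
  group binned none/small/moderate/large at 0.2/0.5/0.8.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

`examples/detect_arousals.py` trains a miniature U-net on eight synthetic
15-minute records and detects arousals on a held-out record (about a
minute on one CPU):

```
trained 4-block U-net, 8,033 parameters, 4 epochs
best validation AUPRC: 0.803
held-out record: 11 true arousals, 8 detected at threshold 0.25 (TP 8, FP 0, FN 3)
```

The AUPRC line says how well the probability track ranks arousal samples
against the extended labels; the last line is the clinical view — of 11
annotated arousals, 8 were found (each detected event overlaps a manual
one), none were spurious, 3 were missed.

The other examples cover cohort simulation (`simulate_cohort.py`),
event-level evaluation and ArI error (`evaluate_events.py`), and the
group-bias analysis (`bias_analysis.py`). The same capabilities are
available from the shell via the `arousalkit` command
(`simulate`, `preprocess`, `train`, `detect`, `evaluate`, `bias-report`,
`run-all`).

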