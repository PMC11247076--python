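"""Train a miniature U-net on synthetic records and detect arousals.

Uses a deliberately tiny cohort and network so the whole script runs in
about a minute on one CPU; the printed validation AUPRC shows how well
the probability track ranks arousal samples, and the detected events are
compared against the ground truth of one held-out record.
"""

import numpy as np

from arousalkit import PostprocessConfig, UNetSpec, TrainConfig
from arousalkit.events import optimize_threshold, probs_to_segments, segments_to_events
from arousalkit.metrics import match_events
from arousalkit.pipeline import detect_record, prepare_training_record
from arousalkit.synth import SynthConfig, generate_recording
from arousalkit.train import train_model

cfg = SynthConfig(duration_s=900.0, target_ari=30.0)
rng = np.random.default_rng(5)
records, truths = [], []
for i in range(8):
    rec, events, hyp, _ = generate_recording(cfg, rng, record_id=f"r{i}")
    records.append(prepare_training_record(rec, events))
    truths.append(events)

spec = UNetSpec(depth=2, base_filters=4, kernel=21, pool_factor=4)
train_cfg = TrainConfig(max_epochs=4, early_stop_patience=4, batch_size=4,
                        chunk_samples=2048, seed=0)
model, history = train_model(spec, records[:6], records[6:], train_cfg)
print(f"trained {spec.n_blocks}-block U-net, "
      f"{spec.param_count():,} parameters, {len(history)} epochs")
print(f"best validation AUPRC: {max(h['val_auprc'] for h in history):.3f}")

post = PostprocessConfig(threshold=0.5)
_, p = detect_record(model, records[7], post)
thr = optimize_threshold([(p, truths[7])], cfg=post)
pred = segments_to_events(probs_to_segments(p), PostprocessConfig(threshold=thr))
c = match_events(truths[7], pred)
print(f"held-out record: {len(truths[7])} true arousals, "
      f"{len(pred)} detected at threshold {thr:.2f} "
      f"(TP {c.tp}, FP {c.fp}, FN {c.fn})")
# A detected event counts as a true positive when it overlaps a manual
# event; each event is at least 15 s because detection runs on labels
# extended by -2 s/+10 s around the scored arousal.
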