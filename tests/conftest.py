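import numpy as np
import pytest


from arousalkit.synth import SynthConfig, generate_recording


@pytest.fixture(scope="session")
def short_recording():
    """One deterministic 10-minute synthetic recording with its truth."""
    cfg = SynthConfig(duration_s=600.0, target_ari=20.0, seed=8)
    rec, events, hyp, meta = generate_recording(cfg, np.random.default_rng(8))
    return rec, events, hyp, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_events(seg, threshold, patience_s, min_event_s, segment_s=1.0):
    """Independent gap-scan oracle: binarize, then walk second-by-second
    fusing positive runs whose gaps are <= patience, then length-filter."""
    pos = [i for i, v in enumerate(seg) if v >= threshold]
    if not pos:
        return []
    events = []
    start = prev = pos[0]
    for i in pos[1:]:
        gap = (i - prev - 1) * segment_s
        if gap <= patience_s:
            prev = i
        else:
            events.append((start * segment_s, (prev + 1) * segment_s))
            start = prev = i
    events.append((start * segment_s, (prev + 1) * segment_s))
    return [(lo, hi) for lo, hi in events if hi - lo >= min_event_s]


def brute_force_auprc(scores, labels):
    """Exhaustive-threshold area under the precision-recall curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    thresholds = np.unique(scores)[::-1]
    pts = []  # (recall, precision), descending threshold
    n_pos = labels.sum()
    for thr in thresholds:
        sel = scores >= thr
        tp = int((labels[sel] == 1).sum())
        fp = int((labels[sel] == 0).sum())
        pts.append((tp / n_pos, tp / (tp + fp)))
    area = 0.0
    prev_r = 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return area


def union_length(intervals):
    """Total length of the union of (lo, hi) intervals."""
    ivs = sorted(intervals)
    total = 0.0
    cur = None
    for lo, hi in ivs:
        if cur is None or lo > cur[1]:
            if cur:
                total += cur[1] - cur[0]
            cur = [lo, hi]
        else:
            cur[1] = max(cur[1], hi)
    if cur:
        total += cur[1] - cur[0]
    return total
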