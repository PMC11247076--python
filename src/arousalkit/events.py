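"""Probability-track to event conversion and decision-threshold tuning.

The 50 Hz probability track is first averaged into one-second segments,
then binarized at a threshold; positive runs separated by gaps up to a
patience are fused into one event, and events shorter than a minimum
length are discarded.  The default minimum of 15 s matches detection on
extended labels (a 3 s arousal plus the -2 s/+10 s label extension); when
detecting on raw labels the AASM floor of 3 s applies instead
(``PostprocessConfig.for_raw_labels``).

The threshold is chosen on a validation set by maximizing micro event F1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io_psg import EventList
from .metrics import ConfusionCounts, match_events
from .preprocess import FS_MODEL

__all__ = [
    "PostprocessConfig",
    "probs_to_segments",
    "segments_to_events",
    "optimize_threshold",
    "DEFAULT_THRESHOLD_GRID",
]

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))


@dataclass(frozen=True)
class PostprocessConfig:
    """Event-conversion parameters.

    threshold   : decision threshold on segment-averaged probability.
    segment_s   : averaging window (1 s).
    patience_s  : maximum gap between positive runs fused into one event.
    min_event_s : shortest event kept (15 s with extended labels).
    aasm_min_s  : the AASM minimum arousal length, used in place of
                  ``min_event_s`` when labels are not extended.
    """

    threshold: float = 0.5
    segment_s: float = 1.0
    patience_s: float = 3.0
    min_event_s: float = 15.0
    aasm_min_s: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.patience_s < 0:
            raise ValueError("patience_s must be >= 0")
        if self.min_event_s < self.aasm_min_s:
            raise ValueError("min_event_s must be >= aasm_min_s")

    def for_raw_labels(self) -> "PostprocessConfig":
        """Variant applying the AASM 3 s minimum instead of 15 s."""
        return replace(self, min_event_s=self.aasm_min_s)


def probs_to_segments(p: np.ndarray, segment_s: float = 1.0, fs: float = FS_MODEL) -> np.ndarray:
    """Average a probability track into ``segment_s``-second segments.

    A trailing partial segment is averaged over the samples it actually
    contains.
    """
    p = np.asarray(p, dtype=float)
    w = int(round(segment_s * fs))
    if w < 1 or len(p) < w:
        raise ValueError(f"track of {len(p)} samples shorter than one segment ({w})")
    n_full = len(p) // w
    out = p[: n_full * w].reshape(n_full, w).mean(axis=1)
    if len(p) > n_full * w:
        out = np.append(out, p[n_full * w :].mean())
    return out


def segments_to_events(
    seg: np.ndarray, cfg: PostprocessConfig, label: str = "Arousal"
) -> EventList:
    """Binarize, fuse runs across short gaps, and length-filter.

    1. positive iff ``seg[k] >= threshold``;
    2. runs of positives separated by a gap ``<= patience_s`` are merged;
    3. merged events shorter than ``min_event_s`` are dropped.
    """
    seg = np.asarray(seg, dtype=float)
    pos = seg >= cfg.threshold
    if not pos.any():
        return EventList()
    dt = cfg.segment_s
    # run-length boundaries of positive stretches, in segment units
    edges = np.diff(pos.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if pos[0]:
        starts.insert(0, 0)
    if pos[-1]:
        ends.append(len(pos))
    merged: list[list[float]] = []
    for s, e in zip(starts, ends):
        lo, hi = s * dt, e * dt
        if merged and lo - merged[-1][1] <= cfg.patience_s:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])
    return EventList(
        (lo, hi - lo, label) for lo, hi in merged if hi - lo >= cfg.min_event_s
    )


def optimize_threshold(
    val_set: Sequence[tuple[np.ndarray, EventList]],
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    cfg: PostprocessConfig | None = None,
    fs: float = FS_MODEL,
) -> float:
    """Grid-search the threshold maximizing micro event F1 on a validation
    set of ``(probability_track, truth_events)`` pairs.

    Ties break toward the lower threshold (more sensitive detector).
    """
    if not val_set:
        raise ValueError("empty validation set")
    if not grid:
        raise ValueError("empty threshold grid")
    cfg = cfg or PostprocessConfig()
    segs = [probs_to_segments(p, cfg.segment_s, fs) for p, _ in val_set]
    best_thr, best_f1 = None, -1.0
    for thr in sorted(float(g) for g in grid):
        c = ConfusionCounts()
        for seg, (_, truth) in zip(segs, val_set):
            pred = segments_to_events(seg, PostprocessConfig(
                threshold=thr,
                segment_s=cfg.segment_s,
                patience_s=cfg.patience_s,
                min_event_s=cfg.min_event_s,
                aasm_min_s=cfg.aasm_min_s,
            ))
            c = c + match_events(truth, pred)
        denom = 2 * c.tp + c.fp + c.fn
        f1 = 2 * c.tp / denom if denom else 0.0
        if f1 > best_f1:
            best_thr, best_f1 = thr, f1
    return float(best_thr)
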