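"""Sample-based and event-based evaluation.

Two complementary views of detector quality are computed:

* **sample level** — the area under the precision-recall curve (AUPRC) of
  the 50 Hz probability track against the binary label track; insensitive
  to how probabilities are later cut into events.
* **event level** — predicted events are matched to manual events by
  interval overlap and pooled into a micro F1; clinically, the arousal
  index (ArI, events per hour of sleep) is computed for both annotations
  and the absolute per-record difference (the ArI error) summarizes the
  impact a detector would have on a sleep report.

Overlap matching uses asymmetric special rules for multiple overlaps:
several predicted events on one manual event count one true positive and
one false negative per extra prediction (the detector fragmented one
arousal); one predicted event spanning several manual events counts every
manual event as detected but adds one false positive per extra manual
event (the detector fused arousals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st
from sklearn.metrics import average_precision_score

from .io_psg import EventList, Hypnogram

__all__ = [
    "ConfusionCounts",
    "RecordEval",
    "EvalReport",
    "sample_auprc",
    "match_events",
    "micro_f1",
    "arousal_index",
    "evaluate_record",
    "evaluate_set",
    "UndefinedMetricError",
]


class UndefinedMetricError(ValueError):
    """The requested metric is mathematically undefined on this input."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def sample_auprc(p: np.ndarray, y: np.ndarray) -> float:
    """Area under the precision-recall curve of score track ``p`` against
    binary labels ``y`` (step-wise integration over all thresholds)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    if y.min() == y.max():
        raise UndefinedMetricError("labels contain a single class; AUPRC undefined")
    return float(average_precision_score(y, p))


def _assert_disjoint(e: EventList, name: str) -> None:
    iv = e.intervals()
    if len(iv) > 1 and np.any(iv[1:, 0] < iv[:-1, 1]):
        raise ValueError(f"{name} events overlap each other")


def match_events(truth: EventList, pred: EventList) -> ConfusionCounts:
    """Overlap-match two internally disjoint event lists.

    Overlap means a nonempty intersection of the half-open intervals.  Let
    ``k_t`` be the number of predictions overlapping manual event ``t`` and
    ``m_p`` the number of manual events overlapping prediction ``p``:

    * TP = number of manual events with ``k_t >= 1``
    * FN = unmatched manual events + ``sum(k_t - 1)`` over matched ones
    * FP = unmatched predictions + ``sum(m_p - 1)`` over matched ones
    """
    _assert_disjoint(truth, "truth")
    _assert_disjoint(pred, "pred")
    tiv = truth.intervals()
    piv = pred.intervals()
    k_t = np.zeros(len(tiv), dtype=int)
    m_p = np.zeros(len(piv), dtype=int)
    for i, (tlo, thi) in enumerate(tiv):
        for j, (plo, phi) in enumerate(piv):
            if plo < thi and tlo < phi:
                k_t[i] += 1
                m_p[j] += 1
    tp = int(np.count_nonzero(k_t))
    fn = int(np.count_nonzero(k_t == 0) + np.maximum(k_t - 1, 0).sum())
    fp = int(np.count_nonzero(m_p == 0) + np.maximum(m_p - 1, 0).sum())
    return ConfusionCounts(tp=tp, fp=fp, fn=fn)


def micro_f1(counts: Iterable[ConfusionCounts]) -> float:
    """F1 from confusion counts summed over records before the ratio."""
    counts = list(counts)
    if not counts:
        raise ValueError("no confusion counts")
    tp = sum(c.tp for c in counts)
    fp = sum(c.fp for c in counts)
    fn = sum(c.fn for c in counts)
    denom = 2 * tp + fp + fn
    if denom == 0:
        raise UndefinedMetricError("no events at all; F1 undefined")
    return 2 * tp / denom


def arousal_index(e: EventList, h: Hypnogram) -> float:
    """Arousals per hour of sleep: ``len(e) / TST_hours``."""
    tst_h = h.total_sleep_time_s() / 3600.0
    if tst_h <= 0:
        raise UndefinedMetricError("zero total sleep time; ArI undefined")
    return len(e) / tst_h


@dataclass(frozen=True)
class RecordEval:
    """Evaluation of one recording."""

    record_id: str
    counts: ConfusionCounts
    ari_true: float
    ari_pred: float
    auprc: float | None = None

    @property
    def ari_error(self) -> float:
        return abs(self.ari_pred - self.ari_true)

    @property
    def ari_diff(self) -> float:
        """Signed difference (prediction minus annotation)."""
        return self.ari_pred - self.ari_true


@dataclass(frozen=True)
class EvalReport:
    """Aggregate over a record set: micro F1, ArI-error statistics, and the
    Pearson correlation of predicted vs annotated ArI."""

    rows: tuple[RecordEval, ...]
    f1: float
    ari_error_mean: float
    ari_error_sd: float
    ari_error_median: float
    ari_error_iqr: tuple[float, float]
    ari_pearson_r: float | None
    mean_auprc: float | None


def evaluate_record(
    record_id: str,
    truth: EventList,
    pred: EventList,
    hypnogram: Hypnogram,
    p: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> RecordEval:
    """Event matching plus ArI for one record; AUPRC if tracks are given."""
    counts = match_events(truth, pred)
    auprc = sample_auprc(p, y) if p is not None and y is not None else None
    return RecordEval(
        record_id=record_id,
        counts=counts,
        ari_true=arousal_index(truth, hypnogram),
        ari_pred=arousal_index(pred, hypnogram),
        auprc=auprc,
    )


def evaluate_set(rows: Sequence[RecordEval]) -> EvalReport:
    """Pool per-record evaluations into the aggregate report.

    Pearson r over (annotated, predicted) ArI pairs needs at least two
    records; zero variance in either series is reported as missing rather
    than forced to a value.
    """
    if not rows:
        raise ValueError("no records to aggregate")
    errs = np.array([r.ari_error for r in rows], dtype=float)
    f1 = micro_f1([r.counts for r in rows])
    if len(rows) < 2:
        raise UndefinedMetricError("need >= 2 records for the ArI correlation")
    a = np.array([r.ari_true for r in rows])
    b = np.array([r.ari_pred for r in rows])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r_val: float | None = None
    else:
        r_val = float(_st.pearsonr(a, b).statistic)
    aup = [r.auprc for r in rows if r.auprc is not None]
    return EvalReport(
        rows=tuple(rows),
        f1=f1,
        ari_error_mean=float(errs.mean()),
        ari_error_sd=float(errs.std(ddof=1)) if len(errs) > 1 else 0.0,
        ari_error_median=float(np.median(errs)),
        ari_error_iqr=(float(np.percentile(errs, 25)), float(np.percentile(errs, 75))),
        ari_pearson_r=r_val,
        mean_auprc=float(np.mean(aup)) if aup else None,
    )
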