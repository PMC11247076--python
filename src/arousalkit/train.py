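"""Training: participant-wise splitting, augmentation, the cyclic-LR Adam
loop with early stopping on validation AUPRC, and the LR range test.

The loss is binary cross entropy on the 50 Hz logits.  The learning rate
follows a triangular cycle between ``lr_high`` and ``lr_low`` with a
four-epoch half-period: it starts at ``lr_high``, reaches ``lr_low`` after
``cycle_epochs`` epochs and returns after twice that.  Per iteration, one
channel is drawn per signal role (montage regularization) and each channel
is scaled by an independent random factor in ``[noise_low, noise_high]``.
Training stops when validation sample-AUPRC has not improved for
``early_stop_patience`` epochs; the best-AUPRC weights are restored.

Batches are random fixed-length chunks; because arousals are rare, half of
the drawn chunks are forced to contain at least one positive sample, which
keeps gradients informative at low prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _nn
from .metrics import UndefinedMetricError, sample_auprc
from .model import UNet1D, UNetSpec, build_model, predict
from .preprocess import ProcessedInput

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "TrainRecord",
    "make_split",
    "augment",
    "cyclic_lr",
    "train_model",
    "lr_range_test",
    "suggest_lr_bounds",
]


@dataclass(frozen=True)
class TrainConfig:
    lr_low: float = 0.00075
    lr_high: float = 0.003
    cycle_epochs: int = 4
    early_stop_patience: int = 15
    noise_low: float = 0.8
    noise_high: float = 1.3
    batch_size: int = 8
    max_epochs: int = 150
    chunk_samples: int = 4096
    pos_chunk_frac: float = 0.5
    additive_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_low < self.lr_high:
            raise ValueError("need 0 < lr_low < lr_high")
        if self.noise_low > self.noise_high:
            raise ValueError("need noise_low <= noise_high")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class SplitPlan:
    """Participant-wise assignment; all recordings of a patient share a split."""

    assignment: dict[str, str]  # patient id -> "train" | "val" | "test"

    def patients(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]


def make_split(
    patients: Sequence[str],
    test_ids: Sequence[str] = (),
    val_frac: float = 0.2,
    seed: int = 0,
) -> SplitPlan:
    """Assign patients to train/val/test, 80/20 among non-test patients.

    ``test_ids`` pins patients to the test split; unknown ids raise.
    """
    patients = list(patients)
    if len(set(patients)) != len(patients):
        raise ValueError("patient ids must be unique")
    unknown = set(test_ids) - set(patients)
    if unknown:
        raise ValueError(f"test ids not in patient list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rest = [p for p in patients if p not in set(test_ids)]
    perm = list(rng.permutation(rest))
    n_val = int(round(val_frac * len(rest)))
    assignment = {p: "test" for p in test_ids}
    assignment.update({p: "val" for p in perm[:n_val]})
    assignment.update({p: "train" for p in perm[n_val:]})
    return SplitPlan(assignment)


@dataclass
class TrainRecord:
    """One preprocessed recording ready for training.

    ``channel_pool`` maps each role to one or more normalized 50 Hz rows so
    the per-iteration channel choice can be re-drawn; ``y`` is the extended,
    rasterized label track of the same length.
    """

    record_id: str
    channel_pool: dict[str, list[np.ndarray]]
    y: np.ndarray

    def __post_init__(self) -> None:
        t = len(self.y)
        for role, rows in self.channel_pool.items():
            if not rows:
                raise ValueError(f"role {role!r} has no channels")
            for r in rows:
                if len(r) != t:
                    raise ValueError(f"role {role!r}: row length {len(r)} != {t}")

    def draw_input(self, rng: np.random.Generator) -> np.ndarray:
        rows = [
            pool[int(rng.integers(len(pool)))]
            for pool in (
                self.channel_pool["EEG"],
                self.channel_pool["EOG"],
                self.channel_pool["EMG"],
            )
        ]
        return np.stack(rows).astype(np.float32)


def augment(x: ProcessedInput | np.ndarray, cfg: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    """Scale each channel by an independent factor ~ U[noise_low, noise_high]
    (or add scaled white noise when ``additive_noise`` is set)."""
    arr = x.x if isinstance(x, ProcessedInput) else np.asarray(x)
    factors = rng.uniform(cfg.noise_low, cfg.noise_high, size=(arr.shape[0], 1))
    if cfg.additive_noise:
        return (arr + (factors - 1.0) * rng.standard_normal(arr.shape)).astype(np.float32)
    return (arr * factors).astype(np.float32)


def cyclic_lr(epoch: int, cfg: TrainConfig) -> float:
    """Triangular schedule: lr_high at epoch 0, lr_low after ``cycle_epochs``
    epochs, back to lr_high after twice that, repeating."""
    period = 2 * cfg.cycle_epochs
    ph = epoch % period
    if ph <= cfg.cycle_epochs:
        frac = ph / cfg.cycle_epochs
    else:
        frac = (period - ph) / cfg.cycle_epochs
    return cfg.lr_high + (cfg.lr_low - cfg.lr_high) * frac


def _chunk_start(
    rec: TrainRecord, chunk: int, want_positive: bool, rng: np.random.Generator
) -> int:
    t = len(rec.y)
    if t <= chunk:
        return 0
    if want_positive:
        pos = np.flatnonzero(rec.y)
        if len(pos):
            center = int(pos[int(rng.integers(len(pos)))])
            lo = max(0, min(center - chunk // 2, t - chunk))
            return lo
    return int(rng.integers(t - chunk + 1))


def _validation_auprc(model: UNet1D, val: Sequence[TrainRecord]) -> float:
    ps, ys = [], []
    for rec in val:
        x = np.stack(
            [rec.channel_pool[role][0] for role in ("EEG", "EOG", "EMG")]
        ).astype(np.float32)
        ps.append(predict(model, x))
        ys.append(rec.y)
    return sample_auprc(np.concatenate(ps), np.concatenate(ys))


def train_model(
    spec: UNetSpec,
    train_records: Sequence[TrainRecord],
    val_records: Sequence[TrainRecord],
    cfg: TrainConfig,
    steps_per_epoch: int | None = None,
) -> tuple[UNet1D, list[dict]]:
    """Train a U-net; returns the best-validation-AUPRC checkpoint and the
    per-epoch history (epoch, lr, train_loss, val_auprc)."""
    if not train_records or not val_records:
        raise ValueError("empty train or validation stream")
    if not any(r.y.any() for r in train_records):
        raise UndefinedMetricError("no positive labels in training data")
    if not any(r.y.any() for r in val_records):
        raise UndefinedMetricError("no positive labels in validation data")

    rng = np.random.default_rng(cfg.seed)
    model = build_model(spec, seed=cfg.seed)
    opt = _nn.AdamState(model.params)
    chunk = (cfg.chunk_samples // spec.divisor) * spec.divisor
    if chunk == 0:
        raise ValueError("chunk_samples smaller than the network's pool divisor")
    if steps_per_epoch is None:
        # at least ~2 passes over the chunk inventory, and never fewer than
        # 25 updates: an "epoch" must move a small cohort's weights
        total = sum(max(1, len(r.y) // chunk) for r in train_records)
        steps_per_epoch = max(25, 2 * total // cfg.batch_size)

    history: list[dict] = []
    best_auprc = -np.inf
    best_weights = model.copy_weights()
    stale = 0
    for epoch in range(cfg.max_epochs):
        lr = cyclic_lr(epoch, cfg)
        losses = []
        for _ in range(steps_per_epoch):
            xb = np.empty((cfg.batch_size, 3, chunk), dtype=np.float32)
            yb = np.empty((cfg.batch_size, chunk), dtype=np.float32)
            for b in range(cfg.batch_size):
                rec = train_records[int(rng.integers(len(train_records)))]
                want_pos = rng.random() < cfg.pos_chunk_frac
                s = _chunk_start(rec, chunk, want_pos, rng)
                x = rec.draw_input(rng)[:, s : s + chunk]
                if x.shape[1] < chunk:  # short record: pad to chunk
                    pad = chunk - x.shape[1]
                    x = np.pad(x, ((0, 0), (0, pad)))
                    yb[b] = np.pad(rec.y[s:].astype(np.float32), (0, pad))
                else:
                    yb[b] = rec.y[s : s + chunk]
                xb[b] = augment(x, cfg, rng)
            z = model.forward_logits(xb, keep_cache=True)
            loss, dz = _nn.bce_with_logits(z, yb)
            grads = model.backward(dz)
            opt.step(model.params, grads, lr)
            losses.append(loss)
        val_auprc = _validation_auprc(model, val_records)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)) if losses else float("nan"),
                "val_auprc": val_auprc,
            }
        )
        if val_auprc > best_auprc:
            best_auprc = val_auprc
            best_weights = model.copy_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    model.set_weights(best_weights)
    return model, history


# ---------------------------------------------------------------------------
# learning-rate range test
# ---------------------------------------------------------------------------


def suggest_lr_bounds(
    lrs: Sequence[float], losses: Sequence[float], flat_tol: float = 1e-3
) -> tuple[float, float]:
    """Pick (lr_low, lr_high) from a loss-vs-LR probe curve.

    ``lr_high`` is the LR at the loss minimum (just before divergence);
    ``lr_low`` is the LR where the descent is steepest.  A curve that never
    improves by more than ``flat_tol`` relative to its start returns the
    full grid span with a warning.
    """
    import warnings

    lrs = np.asarray(lrs, dtype=float)
    losses = np.asarray(losses, dtype=float)
    if len(lrs) != len(losses) or len(lrs) == 0:
        raise ValueError("lrs and losses must be equal-length, non-empty")
    if np.any(np.diff(lrs) <= 0):
        raise ValueError("LR grid must be strictly increasing")
    if len(lrs) == 1:
        return float(lrs[0]), float(lrs[0])
    if losses.min() > losses[0] * (1 + flat_tol):
        raise RuntimeError("loss diverges at every probed LR")
    if losses[0] - losses.min() <= flat_tol * max(abs(losses[0]), 1.0):
        warnings.warn("loss flat across the LR grid; returning full span")
        return float(lrs[0]), float(lrs[-1])
    i_min = int(np.argmin(losses))
    slopes = np.diff(losses) / np.diff(np.log(lrs))
    i_steep = int(np.argmin(slopes[: max(1, i_min)]))
    return float(lrs[i_steep]), float(lrs[i_min])


def lr_range_test(
    spec: UNetSpec,
    train_records: Sequence[TrainRecord],
    lr_grid: Sequence[float],
    cfg: TrainConfig | None = None,
    steps_per_lr: int = 8,
) -> tuple[float, float]:
    """Probe each LR with a short fresh-model run and suggest cycle bounds."""
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    chunk = (cfg.chunk_samples // spec.divisor) * spec.divisor
    losses = []
    for lr in lr_grid:
        model = build_model(spec, seed=cfg.seed)
        opt = _nn.AdamState(model.params)
        last = np.inf
        for _ in range(steps_per_lr):
            rec = train_records[int(rng.integers(len(train_records)))]
            s = _chunk_start(rec, chunk, True, rng)
            x = rec.draw_input(rng)[:, s : s + chunk]
            if x.shape[1] < chunk:
                x = np.pad(x, ((0, 0), (0, chunk - x.shape[1])))
                y = np.pad(rec.y[s:].astype(np.float32), (0, chunk - len(rec.y[s:])))
            else:
                y = rec.y[s : s + chunk].astype(np.float32)
            z = model.forward_logits(x[None], keep_cache=True)
            loss, dz = _nn.bce_with_logits(z, y[None])
            grads = model.backward(dz)
            opt.step(model.params, grads, lr)
            last = loss
        losses.append(last)
    return suggest_lr_bounds(list(lr_grid), losses)
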