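"""End-to-end pipeline: simulate -> preprocess -> train -> detect ->
evaluate -> bias report, driven by a single YAML-able configuration with
one global seed fanned out deterministically to every stage.

Every stage writes its artifacts under the configured output directory and
the run ends with a ``manifest.json`` recording the configuration hash,
derived seeds, artifact names, and headline metrics, so that re-running
the same configuration can be verified to reproduce the same outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .events import (
    DEFAULT_THRESHOLD_GRID,
    PostprocessConfig,
    optimize_threshold,
    probs_to_segments,
    segments_to_events,
)
from .io_psg import (
    EventList,
    Hypnogram,
    Recording,
    read_events,
    read_hypnogram,
    read_metadata_table,
    read_recording,
    write_events,
)
from .metrics import evaluate_record, evaluate_set
from .model import UNet1D, UNetSpec, build_model, predict
from .preprocess import (
    FS_MODEL,
    antialias_resample,
    extend_labels,
    moving_normalize,
    rasterize_labels,
)
from .stats import group_bias_analysis
from .synth import SynthConfig, generate_cohort
from .train import TrainConfig, TrainRecord, make_split, train_model

__all__ = [
    "ConfigError",
    "prepare_training_record",
    "detect_record",
    "validate_config",
    "run_pipeline",
]

_CHANNEL_MAP = {"EEG": ["C3:A2", "C4:A1"], "EOG": ["EOG-L", "EOG-R"], "EMG": ["Chin"]}


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the field."""


def prepare_training_record(
    rec: Recording,
    events: EventList,
    fs_model: float = FS_MODEL,
    window_s: float = 1080.0,
    pre_s: float = 2.0,
    post_s: float = 10.0,
) -> TrainRecord:
    """Preprocess every channel of every role and build the extended,
    rasterized label track for one recording."""
    n_t = round(rec.duration_s * fs_model)
    pool: dict[str, list[np.ndarray]] = {}
    for role in ("EEG", "EOG", "EMG"):
        rows = []
        for name in rec.channels_for(role):
            x = antialias_resample(rec.signals[name], rec.sample_rate[name], fs_model)
            if len(x) != n_t:
                x = x[:n_t] if len(x) > n_t else np.pad(x, (0, n_t - len(x)))
            rows.append(moving_normalize(x, fs_model, window_s).astype(np.float32))
        pool[role] = rows
    ext = extend_labels(events, pre_s, post_s, rec.duration_s)
    y = rasterize_labels(ext, fs_model, n_t)
    return TrainRecord(record_id=rec.id, channel_pool=pool, y=y)


def detect_record(
    model: UNet1D,
    tr: TrainRecord,
    post_cfg: PostprocessConfig,
    fs_model: float = FS_MODEL,
) -> tuple[EventList, np.ndarray]:
    """Predict the probability track (first channel per role, deterministic)
    and convert it to events."""
    x = np.stack([tr.channel_pool[r][0] for r in ("EEG", "EOG", "EMG")])
    p = predict(model, x.astype(np.float32), fs=fs_model)
    seg = probs_to_segments(p, post_cfg.segment_s, fs_model)
    return segments_to_events(seg, post_cfg), p


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_DEFAULTS: dict[str, dict[str, Any]] = {
    "synth": {},
    "model": {"depth": 3, "base_filters": 8, "kernel": 21, "pool_factor": 4},
    "train": {},
    "postprocess": {},
}


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Normalize and validate a pipeline configuration dictionary.

    Unknown sections/fields and out-of-range values raise
    :class:`ConfigError` naming the offending field.
    """
    cfg = {k: dict(v) if isinstance(v, Mapping) else v for k, v in config.items()}
    known = {"seed", "out_dir", "val_frac", "synth", "model", "train", "postprocess"}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("val_frac", 0.25)
    if "out_dir" not in cfg:
        raise ConfigError("out_dir is required")
    for section, defaults in _DEFAULTS.items():
        sec = {**defaults, **cfg.get(section, {})}
        cls = {
            "synth": SynthConfig,
            "model": UNetSpec,
            "train": TrainConfig,
            "postprocess": PostprocessConfig,
        }[section]
        try:
            obj = cls(**sec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{section}: {exc}") from exc
        cfg[section] = obj
    return cfg


def _config_hash(cfg: Mapping[str, Any]) -> str:
    def enc(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        return str(o)

    blob = json.dumps(cfg, sort_keys=True, default=enc)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Any]:
    """Run the full synthetic pipeline; returns the manifest dictionary.

    Stages: simulate a cohort, preprocess it, train the U-net on a
    participant-wise split, optimize the decision threshold on validation,
    detect and evaluate on the validation records, and (when group sizes
    allow) run the diagnosis-group bias analysis of the ArI error.
    """
    cfg = validate_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    synth_cfg: SynthConfig = cfg["synth"]
    spec: UNetSpec = cfg["model"]
    post_cfg: PostprocessConfig = cfg["postprocess"]

    # one global seed fans out deterministically per stage
    ss = np.random.SeedSequence(cfg["seed"])
    seed_synth, seed_split, seed_train = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    train_cfg = TrainConfig(**{**asdict(cfg["train"]), "seed": seed_train})

    # -- simulate ----------------------------------------------------------
    data_dir = out_dir / "data"
    rng = np.random.default_rng(seed_synth)
    ids = generate_cohort(synth_cfg, data_dir, rng=rng)

    # -- load + preprocess -------------------------------------------------
    metas = read_metadata_table(data_dir / "metadata.csv")
    records: dict[str, TrainRecord] = {}
    truths: dict[str, EventList] = {}
    hyps: dict[str, Hypnogram] = {}
    for rid in ids:
        rec = read_recording(
            data_dir / f"{rid}.edf", _CHANNEL_MAP, recording_id=rid, meta=metas[rid]
        )
        truth = read_events(data_dir / f"{rid}.events.tsv")
        records[rid] = prepare_training_record(rec, truth)
        truths[rid] = truth
        hyps[rid] = read_hypnogram(data_dir / f"{rid}.hyp.txt")

    # -- split (each synthetic record is its own participant) --------------
    plan = make_split(ids, val_frac=cfg["val_frac"], seed=seed_split)
    train_ids = plan.patients("train")
    val_ids = plan.patients("val")
    assert not (set(train_ids) & set(val_ids)), "participant leakage"

    # -- train -------------------------------------------------------------
    model, history = train_model(
        spec,
        [records[r] for r in train_ids],
        [records[r] for r in val_ids],
        train_cfg,
    )
    model.save(out_dir / "model.npz")
    with open(out_dir / "history.csv", "w") as fh:
        fh.write("epoch,lr,train_loss,val_auprc\n")
        for h in history:
            fh.write(f"{h['epoch']},{h['lr']:.6g},{h['train_loss']:.6g},{h['val_auprc']:.6g}\n")

    # -- threshold + detection + evaluation on validation ------------------
    val_tracks = {}
    for rid in val_ids:
        _, p = detect_record(model, records[rid], post_cfg)
        val_tracks[rid] = p
    thr = optimize_threshold(
        [(val_tracks[r], truths[r]) for r in val_ids],
        DEFAULT_THRESHOLD_GRID,
        post_cfg,
    )
    post_opt = PostprocessConfig(
        threshold=thr,
        segment_s=post_cfg.segment_s,
        patience_s=post_cfg.patience_s,
        min_event_s=post_cfg.min_event_s,
        aasm_min_s=post_cfg.aasm_min_s,
    )
    rows = []
    for rid in val_ids:
        seg = probs_to_segments(val_tracks[rid], post_opt.segment_s)
        pred = segments_to_events(seg, post_opt)
        write_events(pred, out_dir / f"{rid}.pred.tsv")
        y = records[rid].y
        has_both_classes = bool(y.any()) and not bool(y.all())
        rows.append(
            evaluate_record(
                rid, truths[rid], pred, hyps[rid],
                p=val_tracks[rid] if has_both_classes else None,
                y=y if has_both_classes else None,
            )
        )
    report = evaluate_set(rows)

    # -- bias report (only when the cohort supports it) ---------------------
    bias: dict[str, Any] | None = None
    errors_by_group: dict[str, list[float]] = {}
    for row in rows:
        for g in metas[row.record_id].diagnosis_groups:
            errors_by_group.setdefault(g, []).append(row.ari_error)
    usable = {g: v for g, v in errors_by_group.items() if len(v) >= 3}
    if len(usable) >= 2 and "NormalFinding" in usable:
        gc = group_bias_analysis(usable)
        bias = {
            g: {"n": r.n, "cohens_d": r.cohens_d, "effect_bin": r.effect_bin,
                "significant": r.significant}
            for g, r in gc.results.items()
        }

    manifest = {
        "version": __version__,
        "config_hash": _config_hash(
            {k: v for k, v in cfg.items() if k != "out_dir"}
        ),
        "seeds": {"synth": seed_synth, "split": seed_split, "train": seed_train},
        "n_records": len(ids),
        "split": {"train": sorted(train_ids), "val": sorted(val_ids)},
        "threshold": thr,
        "epochs_run": len(history),
        "best_val_auprc": max(h["val_auprc"] for h in history),
        "val_prevalence": float(
            np.concatenate([records[r].y for r in val_ids]).mean()
        ),
        "metrics": {
            "f1": report.f1,
            "ari_error_mean": report.ari_error_mean,
            "ari_error_median": report.ari_error_median,
            "ari_pearson_r": report.ari_pearson_r,
        },
        "bias": bias,
        "artifacts": sorted(
            p.name for p in out_dir.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
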