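"""Synthetic polysomnogram generator.

Produces overnight multichannel recordings with ground-truth arousal
events, hypnograms, and clinical metadata so that the whole detection
pipeline can be exercised and tested without any real data.

What is emulated
----------------
* a semi-Markov hypnogram with wake/NREM/REM cycling in 30 s epochs;
* stage-dependent background EEG (1/f colored noise with a stage
  amplitude envelope, deep sleep being larger and slower), slow EOG
  activity, and high-frequency chin EMG whose tone drops from wake to
  REM atonia;
* arousals as additive band-limited (12-20 Hz by default) EEG bursts —
  an abrupt spectral shift against the background — lasting 3-15 s, with
  at least 10 s of sleep before each event, at a configurable hourly rate;
  during stage R the chin-EMG amplitude rises simultaneously;
* diagnosis-group, age and sex metadata with clinically plausible
  marginals.

What is deliberately not emulated: physiologically realistic EEG
microstructure (spindles, K-complexes), respiratory or leg-movement
events, artifacts.  The generator provides statistical structure for
testing, not a sleep simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_psg import (
    EventList,
    Hypnogram,
    Recording,
    RecordingMeta,
    write_edf,
    write_events,
    write_hypnogram,
    write_metadata_table,
)

__all__ = [
    "SynthConfig",
    "generate_hypnogram",
    "generate_events",
    "generate_meta",
    "generate_recording",
    "generate_cohort",
    "simulate_predictions",
]

_EEG_CHANNELS = ("C3:A2", "C4:A1")
_EOG_CHANNELS = ("EOG-L", "EOG-R")
_EMG_CHANNELS = ("Chin",)

# stage -> (EEG amplitude, EMG amplitude) relative scale
_STAGE_AMP = {
    "W": (0.7, 1.2),
    "N1": (0.9, 0.7),
    "N2": (1.1, 0.55),
    "N3": (1.8, 0.45),
    "R": (0.9, 0.3),
}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a plausible clinical night: 6 h records at 200 Hz
    with an arousal index of 25/h (clinical cohorts average roughly
    19-27/h), arousal durations uniform on 3-15 s, and at least 10 s of
    sleep preceding each arousal.
    """

    n_records: int = 30
    duration_s: float = 21600.0
    fs: float = 200.0
    target_ari: float = 25.0
    arousal_dur_range: tuple[float, float] = (3.0, 15.0)
    min_gap_s: float = 10.0
    burst_band: tuple[float, float] = (12.0, 20.0)
    burst_gain: float = 2.0
    emg_burst_gain: float = 3.0
    noise_exponent: float = 1.0
    therapy_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.arousal_dur_range
        if not (3.0 <= lo <= hi <= 15.0):
            raise ValueError("arousal durations must stay within [3, 15] s")
        if self.target_ari <= 0:
            raise ValueError("target_ari must be positive")
        mean_spacing = 3600.0 / self.target_ari
        if mean_spacing <= self.min_gap_s + hi:
            raise ValueError(
                f"target_ari={self.target_ari}/h infeasible with a "
                f"{self.min_gap_s} s gap and {hi} s events"
            )
        if self.duration_s < 60:
            raise ValueError("duration_s too short for a hypnogram")


# ---------------------------------------------------------------------------
# hypnogram and events
# ---------------------------------------------------------------------------


def generate_hypnogram(cfg: SynthConfig, rng: np.random.Generator) -> Hypnogram:
    """Semi-Markov stage sequence: brief initial wake, then NREM/REM cycles
    (N3 fading and R growing across the night) with occasional awakenings."""
    n_epochs = int(cfg.duration_s // 30)
    stages: list[str] = []

    def dwell(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    stages += ["W"] * dwell(2, 6)
    cycle = 0
    while len(stages) < n_epochs:
        stages += ["N1"] * dwell(1, 3)
        stages += ["N2"] * dwell(8, 20)
        n3 = max(0, dwell(4, 16) - 4 * cycle)  # deep sleep fades over the night
        stages += ["N3"] * n3
        stages += ["N2"] * dwell(2, 6)
        stages += ["R"] * dwell(2, 6 + 4 * cycle)  # REM grows over the night
        if rng.random() < 0.35:
            stages += ["W"] * dwell(1, 2)
        cycle += 1
    return Hypnogram(stages[:n_epochs])


def _sleep_regions(h: Hypnogram) -> list[tuple[float, float]]:
    """Maximal contiguous non-wake intervals, in seconds."""
    regions: list[tuple[float, float]] = []
    start = None
    for i, s in enumerate(h.stages):
        if s != "W" and start is None:
            start = i * h.epoch_s
        elif s == "W" and start is not None:
            regions.append((start, i * h.epoch_s))
            start = None
    if start is not None:
        regions.append((start, len(h.stages) * h.epoch_s))
    return regions


def generate_events(
    cfg: SynthConfig, hyp: Hypnogram, rng: np.random.Generator
) -> EventList:
    """Renewal process of arousals on sleep time.

    Within each sleep region events arrive with spacing
    ``min_gap + duration + Exp(mean)`` where the exponential mean is chosen
    so the long-run rate equals ``target_ari`` per sleep hour.
    """
    lo_d, hi_d = cfg.arousal_dur_range
    mean_dur = 0.5 * (lo_d + hi_d)
    exp_mean = 3600.0 / cfg.target_ari - cfg.min_gap_s - mean_dur
    events = []
    for reg_lo, reg_hi in _sleep_regions(hyp):
        t = reg_lo
        while True:
            onset = t + cfg.min_gap_s + rng.exponential(exp_mean)
            dur = rng.uniform(lo_d, hi_d)
            if onset + dur > reg_hi:
                break
            events.append((onset, dur, "Arousal"))
            t = onset + dur
    return EventList(events)


def generate_meta(cfg: SynthConfig, rng: np.random.Generator) -> RecordingMeta:
    """Random clinical metadata with sleep-laboratory-like marginals."""
    groups = set()
    for g, p in (
        ("SRBD", 0.73),
        ("SRMD", 0.17),
        ("Insomnia", 0.16),
        ("Hypersomnia", 0.05),
        ("Parasomnia", 0.13),
    ):
        if rng.random() < p:
            groups.add(g)
    if "SRBD" in groups and rng.random() < cfg.therapy_fraction:
        groups.add("SRBD-Therapy")
    if not groups:
        groups.add("NormalFinding")
    return RecordingMeta(
        age=float(np.round(rng.uniform(18, 92), 1)),
        sex=str(rng.choice(["F", "M"])),
        diagnosis_groups=frozenset(groups),
    )


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    spec *= scale
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / max(x.std(), 1e-12)


def _band_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS band-limited noise (FFT brick-wall within ``band``)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    x = np.fft.irfft(spec, n)
    return x / max(x.std(), 1e-12)


def _stage_envelope(hyp: Hypnogram, fs: float, n: int, which: int) -> np.ndarray:
    per_epoch = np.array([_STAGE_AMP[s][which] for s in hyp.stages])
    env = np.repeat(per_epoch, int(round(hyp.epoch_s * fs)))
    if len(env) < n:
        env = np.pad(env, (0, n - len(env)), mode="edge")
    return env[:n]


def _taper(n: int, fs: float, ramp_s: float = 0.5) -> np.ndarray:
    r = min(int(ramp_s * fs), n // 2)
    w = np.ones(n)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        w[:r] = ramp
        w[-r:] = ramp[::-1]
    return w


def generate_recording(
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
    record_id: str = "synth-000",
) -> tuple[Recording, EventList, Hypnogram, RecordingMeta]:
    """Generate one full synthetic recording (deterministic given rng state)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    hyp = generate_hypnogram(cfg, rng)
    events = generate_events(cfg, hyp, rng)
    meta = generate_meta(cfg, rng)
    fs = cfg.fs
    n = round(cfg.duration_s * fs)

    signals: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    eeg_env = _stage_envelope(hyp, fs, n, 0)
    emg_env = _stage_envelope(hyp, fs, n, 1)

    for name in _EEG_CHANNELS:
        x = _colored_noise(n, cfg.noise_exponent, rng) * eeg_env
        for onset, dur, _ in events:
            lo = int(round(onset * fs))
            hi = min(int(round((onset + dur) * fs)), n)
            burst = _band_noise(hi - lo, fs, cfg.burst_band, rng)
            amp = cfg.burst_gain * float(eeg_env[lo:hi].mean())
            x[lo:hi] += amp * burst * _taper(hi - lo, fs)
        signals[name] = x.astype(np.float32)
        rates[name] = fs

    for name in _EOG_CHANNELS:
        x = _colored_noise(n, 2.0, rng)
        rem = np.array([1.6 if s == "R" else 1.0 for s in hyp.stages])
        env = np.repeat(rem, int(round(hyp.epoch_s * fs)))
        env = np.pad(env, (0, max(0, n - len(env))), mode="edge")[:n]
        signals[name] = (x * env).astype(np.float32)
        rates[name] = fs

    for name in _EMG_CHANNELS:
        x = rng.standard_normal(n) * emg_env
        for onset, dur, _ in events:
            if hyp.stage_at(onset) == "R":  # EMG rise is required in stage R
                lo = int(round(onset * fs))
                hi = min(int(round((onset + dur) * fs)), n)
                x[lo:hi] *= 1.0 + (cfg.emg_burst_gain - 1.0) * _taper(hi - lo, fs)
        signals[name] = x.astype(np.float32)
        rates[name] = fs

    rec = Recording(
        id=record_id,
        signals=signals,
        sample_rate=rates,
        roles={
            "EEG": list(_EEG_CHANNELS),
            "EOG": list(_EOG_CHANNELS),
            "EMG": list(_EMG_CHANNELS),
        },
        duration_s=float(cfg.duration_s),
        meta=meta,
    )
    return rec, events, hyp, meta


def simulate_predictions(
    truth: EventList,
    hyp: Hypnogram,
    rng: np.random.Generator,
    fp_per_hour: float = 2.0,
    fn_prob: float = 0.05,
) -> EventList:
    """Emulate an imperfect detector's output from the ground truth.

    Each true event is missed with probability ``fn_prob``; spurious events
    (3-15 s, in sleep) are added at ``fp_per_hour`` per sleep hour.  Used
    to build evaluation fixtures without training a model.
    """
    kept = [(o, d, lab) for o, d, lab in truth if rng.random() >= fn_prob]
    tst_h = hyp.total_sleep_time_s() / 3600.0
    n_spur = rng.poisson(fp_per_hour * tst_h)
    regions = _sleep_regions(hyp)
    total = sum(hi - lo for lo, hi in regions)
    occupied = sorted((o, o + d) for o, d, _ in kept)
    for _ in range(int(n_spur)):
        for _attempt in range(20):
            u = rng.uniform(0, total)
            for lo, hi in regions:
                if u < hi - lo:
                    onset = lo + u
                    break
                u -= hi - lo
            dur = rng.uniform(3.0, 15.0)
            if all(onset + dur <= a or onset >= b for a, b in occupied):
                occupied.append((onset, onset + dur))
                occupied.sort()
                kept.append((onset, dur, "Arousal"))
                break
    return EventList(kept)


def generate_cohort(
    cfg: SynthConfig,
    out_dir: str | Path,
    group_effects: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    base_fp_per_hour: float = 2.0,
) -> list[str]:
    """Write a cohort of record bundles (EDF + events TSV + hypnogram) and a
    metadata table to ``out_dir``; returns the record ids.

    When ``group_effects`` maps group names to spurious-detection-rate
    shifts (events/h added to ``base_fp_per_hour``), records are assigned
    to those groups in a balanced round-robin and a simulated detector
    output (``<id>.pred.tsv``) is written per record, so downstream
    evaluation sees a group-dependent ArI error.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    metas: dict[str, RecordingMeta] = {}
    ids: list[str] = []
    group_names = list(group_effects) if group_effects else []
    for i in range(cfg.n_records):
        rid = f"synth-{i:03d}"
        rec, events, hyp, meta = generate_recording(cfg, rng, record_id=rid)
        if group_names:
            g = group_names[i % len(group_names)]
            meta = RecordingMeta(
                age=meta.age, sex=meta.sex, diagnosis_groups=frozenset({g})
            )
        write_edf(out_dir / f"{rid}.edf", rec.signals, rec.sample_rate)
        write_events(events, out_dir / f"{rid}.events.tsv")
        write_hypnogram(hyp, out_dir / f"{rid}.hyp.txt")
        if group_effects is not None:
            shift = group_effects.get(g, 0.0) if group_names else 0.0
            pred = simulate_predictions(
                events, hyp, rng, fp_per_hour=base_fp_per_hour + shift
            )
            write_events(pred, out_dir / f"{rid}.pred.tsv")
        metas[rid] = meta
        ids.append(rid)
    write_metadata_table(metas, out_dir / "metadata.csv")
    return ids
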