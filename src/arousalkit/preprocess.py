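"""Signal preprocessing: antialias resampling, moving-window normalization,
label extension and rasterization.

The detector consumes a three-channel (EEG, EOG, EMG) input at 50 Hz.  Each
raw channel is low-pass filtered with a linear-phase FIR (delay compensated,
so effectively zero phase — event timing is preserved for overlap matching),
downsampled, and then z-normalized against an 18-minute centered moving
window so that slow drifts in amplitude (electrode impedance, montage
differences between labs) do not reach the model.

Arousal labels are widened by 2 s before onset and 10 s after offset to
cover the autonomic response around the scored EEG shift, then rasterized to
a binary track aligned sample-for-sample with the model input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.signal import firwin, kaiserord, resample_poly

from .io_psg import EventList, Recording

__all__ = [
    "ProcessedInput",
    "antialias_resample",
    "moving_normalize",
    "extend_labels",
    "rasterize_labels",
    "select_channels",
    "preprocess_recording",
    "FS_MODEL",
]

FS_MODEL = 50.0  # model sampling rate, samples/s

_ROLES = ("EEG", "EOG", "EMG")


@dataclass(frozen=True)
class ProcessedInput:
    """Model-ready 3 x T input at ``fs_model`` (rows: EEG, EOG, EMG)."""

    x: np.ndarray
    fs_model: float
    source_channels: tuple[str, str, str]

    def __post_init__(self) -> None:
        if self.x.ndim != 2 or self.x.shape[0] != 3:
            raise ValueError(f"expected 3 x T input, got shape {self.x.shape}")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite values in processed input")

    @property
    def n_samples(self) -> int:
        return self.x.shape[1]


def antialias_resample(
    s: np.ndarray,
    fs_in: float,
    fs_out: float = FS_MODEL,
    *,
    stopband_db: float = 60.0,
) -> np.ndarray:
    """Low-pass filter and resample ``s`` from ``fs_in`` to ``fs_out``.

    A windowed-sinc (Kaiser) FIR with cutoff at the output Nyquist
    (-6 dB at ``fs_out / 2``) and a transition band of 20 % of the output
    Nyquist is applied polyphase; the linear-phase delay is compensated by
    :func:`scipy.signal.resample_poly`, so the output is time-aligned with
    the input.  Output length is ``round(len(s) * fs_out / fs_in)``.

    Raises
    ------
    ValueError
        If ``fs_in < fs_out`` (upsampling is not supported).
    """
    s = np.asarray(s, dtype=float)
    if fs_in < fs_out:
        raise ValueError(f"upsampling not supported ({fs_in} -> {fs_out} Hz)")
    n_out = round(len(s) * fs_out / fs_in)
    if fs_in == fs_out:
        return s.copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    inter_nyq = fs_in * up / 2.0
    cutoff = fs_out / 2.0
    width = 0.2 * cutoff  # transition band, Hz
    numtaps, beta = kaiserord(stopband_db, width / inter_nyq)
    numtaps |= 1  # odd length -> exactly linear phase type I
    h = firwin(numtaps, cutoff / inter_nyq, window=("kaiser", beta))
    out = resample_poly(s, up, down, window=h)
    # resample_poly returns ceil(len*up/down); match the length contract
    if len(out) > n_out:
        out = out[:n_out]
    elif len(out) < n_out:
        out = np.pad(out, (0, n_out - len(out)), mode="edge")
    return out


def moving_normalize(
    s: np.ndarray,
    fs: float,
    window_s: float = 1080.0,
    *,
    eps: float = 1e-8,
) -> np.ndarray:
    """Remove the mean and RMS over a centered moving window.

    ``out[i] = (s[i] - m_i) / max(r_i, eps)`` where ``m_i`` is the mean and
    ``r_i`` the RMS of the mean-removed samples within a window of
    ``window_s`` seconds centered on ``i`` and truncated at the record
    edges.  Cumulative sums make this O(n).

    A constant input maps to all zeros (the ``eps`` guard prevents 0/0).
    """
    s = np.asarray(s, dtype=float)
    n = len(s)
    if n == 0:
        return s.copy()
    half = max(1, int(round(window_s * fs / 2)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)  # exclusive
    c1 = np.concatenate([[0.0], np.cumsum(s)])
    c2 = np.concatenate([[0.0], np.cumsum(s * s)])
    cnt = (hi - lo).astype(float)
    mean = (c1[hi] - c1[lo]) / cnt
    # RMS of the mean-removed window: sqrt(E[x^2] - mean^2)
    var = np.maximum((c2[hi] - c2[lo]) / cnt - mean**2, 0.0)
    rms = np.sqrt(var)
    return (s - mean) / np.maximum(rms, eps)


def extend_labels(
    e: EventList,
    pre_s: float = 2.0,
    post_s: float = 10.0,
    duration_s: float | None = None,
) -> EventList:
    """Widen each event by ``pre_s`` before onset and ``post_s`` after end.

    Extended intervals are clipped to ``[0, duration_s]`` and overlapping
    intervals are merged (a binary label track cannot represent overlap).
    Merged events keep the label of the earliest contributor.
    """
    if not len(e):
        return EventList()
    widened = []
    for onset, dur, lab in e:
        lo = max(0.0, onset - pre_s)
        hi = onset + dur + post_s
        if duration_s is not None:
            hi = min(hi, duration_s)
        if hi > lo:
            widened.append((lo, hi, lab))
    widened.sort()
    merged: list[list] = []
    for lo, hi, lab in widened:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi, lab])
    return EventList((lo, hi - lo, lab) for lo, hi, lab in merged)


def rasterize_labels(e: EventList, fs: float = FS_MODEL, n_samples: int = 0) -> np.ndarray:
    """Binary label track: ``y[t] = 1`` iff sample time ``t / fs`` lies in
    some event interval (half-open).
    """
    y = np.zeros(n_samples, dtype=np.int8)
    for onset, dur, _ in e:
        lo = int(math.ceil(onset * fs - 1e-9))
        hi = int(math.ceil((onset + dur) * fs - 1e-9))
        y[max(lo, 0) : min(hi, n_samples)] = 1
    return y


def select_channels(r: Recording, rng: np.random.Generator) -> tuple[str, str, str]:
    """Draw one channel per role (EEG, EOG, EMG), uniformly at random.

    Random channel choice doubles as a train-time regularizer: the model
    sees every montage variant instead of memorizing a single electrode.
    """
    picks = []
    for role in _ROLES:
        names = r.roles.get(role, [])
        if not names:
            raise ValueError(f"configuration error: no channels for role {role!r}")
        picks.append(names[int(rng.integers(len(names)))])
    return tuple(picks)


def preprocess_recording(
    r: Recording,
    channels: tuple[str, str, str] | None = None,
    *,
    fs_model: float = FS_MODEL,
    window_s: float = 1080.0,
    rng: np.random.Generator | None = None,
) -> ProcessedInput:
    """Full chain: channel choice -> antialias resample -> moving normalize.

    If ``channels`` is None a random triple is drawn with ``rng`` (training
    augmentation); pass an explicit triple for deterministic inference.
    """
    if channels is None:
        channels = select_channels(r, rng or np.random.default_rng())
    n_target = round(r.duration_s * fs_model)
    rows = []
    for name in channels:
        x = antialias_resample(r.signals[name], r.sample_rate[name], fs_model)
        if len(x) != n_target:  # channels of slightly different length
            x = x[:n_target] if len(x) > n_target else np.pad(x, (0, n_target - len(x)))
        rows.append(moving_normalize(x, fs_model, window_s))
    return ProcessedInput(
        x=np.vstack(rows).astype(np.float32), fs_model=fs_model, source_channels=tuple(channels)
    )
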