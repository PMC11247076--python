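"""Polysomnogram I/O: signals, arousal annotations, hypnograms, metadata.

The package's native on-disk layout for one recording is

* ``<id>.edf``        -- multichannel signals (EDF, 16-bit, native rates kept)
* ``<id>.events.tsv`` -- annotations, one row per event: onset_s, duration_s, label
* ``<id>.hyp.txt``    -- hypnogram, one stage symbol (W/N1/N2/N3/R) per line
* cohort-level ``metadata.csv`` with one row per recording

All times are seconds from record start; event intervals are half-open
``[onset, onset + duration)``; hypnogram epoch ``i`` covers ``[30i, 30i+30)``.

The EDF reader/writer here preserves per-channel sampling rates, which is
why the format is handled directly rather than through a loader that
resamples everything to a common rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "RecordingMeta",
    "EventList",
    "Hypnogram",
    "DIAGNOSIS_GROUPS",
    "SLEEP_STAGES",
    "read_recording",
    "write_edf",
    "read_events",
    "write_events",
    "read_hypnogram",
    "write_hypnogram",
    "read_metadata_table",
    "write_metadata_table",
    "eligible_record",
    "PsgIOError",
    "ChannelMissingError",
]

DIAGNOSIS_GROUPS = frozenset(
    {
        "SRBD",
        "SRBD-Therapy",
        "SRMD",
        "Insomnia",
        "Hypersomnia",
        "Parasomnia",
        "NormalFinding",
    }
)

SLEEP_STAGES = ("W", "N1", "N2", "N3", "R")


class PsgIOError(IOError):
    """Unreadable or structurally invalid PSG file."""


class ChannelMissingError(KeyError):
    """A requested channel role has no matching channel in the file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecordingMeta:
    """Per-recording clinical metadata used by the bias analysis.

    ``diagnosis_groups`` follows sleep-laboratory practice: the disorder
    categories are non-exclusive (one night can carry several diagnoses),
    except that a treated-SRBD night cannot simultaneously be a normal
    finding.
    """

    age: float | None = None
    sex: str | None = None
    diagnosis_groups: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        unknown = set(self.diagnosis_groups) - DIAGNOSIS_GROUPS
        if unknown:
            raise ValueError(f"unknown diagnosis groups: {sorted(unknown)}")
        if {"SRBD-Therapy", "NormalFinding"} <= set(self.diagnosis_groups):
            raise ValueError("SRBD-Therapy is exclusive of NormalFinding")


@dataclass
class Recording:
    """A multichannel PSG recording with per-channel native sample rates.

    Parameters
    ----------
    id : str
        Recording identifier.
    signals : mapping of channel name -> 1-D float array.
    sample_rate : mapping of channel name -> samples per second.
    roles : mapping of role ("EEG", "EOG", "EMG") -> list of channel names.
    duration_s : float
        Record duration in seconds.
    meta : RecordingMeta
    """

    id: str
    signals: dict[str, np.ndarray]
    sample_rate: dict[str, float]
    roles: dict[str, list[str]]
    duration_s: float
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for role, names in self.roles.items():
            for name in names:
                if name not in self.signals:
                    raise ChannelMissingError(
                        f"role {role!r} refers to missing channel {name!r}"
                    )
        for name, sig in self.signals.items():
            fs = self.sample_rate[name]
            expect = round(self.duration_s * fs)
            if len(sig) != expect:
                raise ValueError(
                    f"channel {name!r}: length {len(sig)} != "
                    f"round(duration * fs) = {expect}"
                )

    def channels_for(self, role: str) -> list[str]:
        names = self.roles.get(role, [])
        if not names:
            raise ChannelMissingError(f"no channels registered for role {role!r}")
        return names


@dataclass(frozen=True)
class EventList:
    """Ordered, typed intervals in seconds (half-open).

    The constructor normalizes: events are sorted by onset.  Overlap between
    events is allowed here (annotations may overlap); operations that require
    disjoint events validate separately.
    """

    events: tuple[tuple[float, float, str], ...]

    def __init__(self, events: Iterable[tuple[float, float, str]] = ()):
        evs = [(float(o), float(d), str(lab)) for o, d, lab in events]
        for onset, dur, _ in evs:
            if onset < 0:
                raise ValueError(f"negative onset {onset}")
            if dur <= 0:
                raise ValueError(f"non-positive duration {dur}")
        evs.sort(key=lambda e: (e[0], e[1]))
        object.__setattr__(self, "events", tuple(evs))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def intervals(self) -> np.ndarray:
        """(n, 2) array of [onset, end) interval bounds."""
        if not self.events:
            return np.empty((0, 2))
        arr = np.array([(o, o + d) for o, d, _ in self.events])
        return arr

    def total_covered_s(self) -> float:
        """Length of the union of all intervals, in seconds."""
        covered = 0.0
        cur_lo = cur_hi = None
        for lo, hi in self.intervals():
            if cur_hi is None or lo > cur_hi:
                if cur_hi is not None:
                    covered += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        if cur_hi is not None:
            covered += cur_hi - cur_lo
        return covered


@dataclass(frozen=True)
class Hypnogram:
    """Sequence of 30-s sleep-stage epochs (W, N1, N2, N3, R)."""

    stages: tuple[str, ...]
    epoch_s: float = 30.0

    def __init__(self, stages: Iterable[str], epoch_s: float = 30.0):
        st = tuple(str(s) for s in stages)
        bad = set(st) - set(SLEEP_STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages: {sorted(bad)}")
        object.__setattr__(self, "stages", st)
        object.__setattr__(self, "epoch_s", float(epoch_s))

    def __len__(self) -> int:
        return len(self.stages)

    def total_sleep_time_s(self) -> float:
        """Total sleep time: summed duration of non-wake epochs."""
        return self.epoch_s * sum(1 for s in self.stages if s != "W")

    def stage_at(self, t_s: float) -> str:
        i = int(t_s // self.epoch_s)
        if not 0 <= i < len(self.stages):
            raise IndexError(f"time {t_s} s outside hypnogram")
        return self.stages[i]

    def sleep_mask(self) -> np.ndarray:
        return np.array([s != "W" for s in self.stages])


# ---------------------------------------------------------------------------
# EDF signals
# ---------------------------------------------------------------------------

_EDF_HDR = 256


def write_edf(
    path: str | Path,
    signals: Mapping[str, np.ndarray],
    sample_rate: Mapping[str, float],
    *,
    physical_dim: str = "uV",
) -> None:
    """Write channels to a plain EDF file (one-second data records, int16).

    Channel sampling rates must be positive integers and all channels must
    span the same integer number of seconds.  Physical scaling is chosen per
    channel from the data range, so the round-trip error is bounded by
    ``(max - min) / 65535`` per channel.
    """
    path = Path(path)
    names = list(signals)
    if not names:
        raise ValueError("no channels to write")
    rates = []
    for name in names:
        fs = sample_rate[name]
        if fs <= 0 or abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"channel {name!r}: EDF writer needs integer rate, got {fs}")
        rates.append(int(round(fs)))
    durations = {name: len(signals[name]) / fs for name, fs in zip(names, rates)}
    n_rec = durations[names[0]]
    if any(abs(d - n_rec) > 1e-9 for d in durations.values()):
        raise ValueError("channels disagree on total duration")
    if abs(n_rec - round(n_rec)) > 1e-9:
        raise ValueError("EDF writer needs an integer number of seconds")
    n_rec = int(round(n_rec))

    phys_lo, phys_hi, scaled = [], [], []
    dig_lo, dig_hi = -32768, 32767
    for name in names:
        x = np.asarray(signals[name], dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo < 1e-12:  # constant channel: give it a unit range
            lo, hi = lo - 1.0, hi + 1.0
        gain = (dig_hi - dig_lo) / (hi - lo)
        d = np.clip(np.round((x - lo) * gain) + dig_lo, dig_lo, dig_hi)
        phys_lo.append(lo)
        phys_hi.append(hi)
        scaled.append(d.astype("<i2"))
    ns = len(names)

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(_EDF_HDR * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )

    def num(v: float, n: int = 8) -> bytes:
        s = f"{v:.10g}"[:n]
        return pad(s, n)

    sig_hdr = b"".join(
        [
            b"".join(pad(n, 16) for n in names),
            b"".join(pad("", 80) for _ in names),
            b"".join(pad(physical_dim, 8) for _ in names),
            b"".join(num(v) for v in phys_lo),
            b"".join(num(v) for v in phys_hi),
            b"".join(pad(str(dig_lo), 8) for _ in names),
            b"".join(pad(str(dig_hi), 8) for _ in names),
            b"".join(pad("", 80) for _ in names),
            b"".join(pad(str(r), 8) for r in rates),
            b"".join(pad("", 32) for _ in names),
        ]
    )

    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for rec in range(n_rec):
            for name, fs, d in zip(names, rates, scaled):
                fh.write(d[rec * fs : (rec + 1) * fs].tobytes())


def _read_edf(path: Path) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    with open(path, "rb") as fh:
        hdr = fh.read(_EDF_HDR)
        if len(hdr) < _EDF_HDR:
            raise PsgIOError(f"{path}: truncated EDF header")
        try:
            n_rec = int(hdr[236:244])
            rec_dur = float(hdr[244:252])
            ns = int(hdr[252:256])
        except ValueError as exc:
            raise PsgIOError(f"{path}: malformed EDF header") from exc
        sig = fh.read(_EDF_HDR * ns)
        # per-signal header: ns x (label 16 | transducer 80 | dim 8 | pmin 8
        # | pmax 8 | dmin 8 | dmax 8 | prefilter 80 | samples/record 8 | 32)
        pos = 0

        def take(width: int) -> list[str]:
            nonlocal pos
            out = [
                sig[pos + i * width : pos + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]
            pos += width * ns
            return out

        labels = take(16)
        take(80)  # transducer
        take(8)  # physical dimension
        phys_lo = [float(v) for v in take(8)]
        phys_hi = [float(v) for v in take(8)]
        dig_lo = [int(v) for v in take(8)]
        dig_hi = [int(v) for v in take(8)]
        take(80)  # prefiltering
        spr = [int(v) for v in take(8)]  # samples per data record
        take(32)

        rec_len = sum(spr)
        raw = np.frombuffer(fh.read(n_rec * rec_len * 2), dtype="<i2")
        if raw.size != n_rec * rec_len:
            raise PsgIOError(f"{path}: truncated EDF data")
        raw = raw.reshape(n_rec, rec_len)

    signals: dict[str, np.ndarray] = {}
    rates: dict[str, float] = {}
    col = 0
    for i, name in enumerate(labels):
        chunk = raw[:, col : col + spr[i]].reshape(-1).astype(float)
        gain = (phys_hi[i] - phys_lo[i]) / (dig_hi[i] - dig_lo[i])
        signals[name] = phys_lo[i] + (chunk - dig_lo[i]) * gain
        rates[name] = spr[i] / rec_dur
        col += spr[i]
    return signals, rates


def read_recording(
    path: str | Path,
    channel_map: Mapping[str, Sequence[str]],
    *,
    recording_id: str | None = None,
    meta: RecordingMeta | None = None,
) -> Recording:
    """Read an EDF file into a :class:`Recording`.

    Parameters
    ----------
    path : path to the EDF file.
    channel_map : mapping role ("EEG", "EOG", "EMG") -> channel names to use.
        Every named channel must exist in the file; a role whose channels are
        all missing raises :class:`ChannelMissingError` naming the role.
    """
    path = Path(path)
    if not path.exists():
        raise PsgIOError(f"no such file: {path}")
    signals, rates = _read_edf(path)
    roles: dict[str, list[str]] = {}
    for role, wanted in channel_map.items():
        found = [name for name in wanted if name in signals]
        missing = [name for name in wanted if name not in signals]
        if missing:
            raise ChannelMissingError(
                f"role {role!r}: channels {missing} not in file "
                f"(available: {sorted(signals)})"
            )
        if not found:
            raise ChannelMissingError(f"role {role!r}: no channels requested")
        roles[role] = found
    durations = {n: len(s) / rates[n] for n, s in signals.items()}
    duration_s = max(durations.values())
    return Recording(
        id=recording_id or path.stem,
        signals=signals,
        sample_rate=rates,
        roles=roles,
        duration_s=duration_s,
        meta=meta or RecordingMeta(),
    )


# ---------------------------------------------------------------------------
# annotations, hypnograms, metadata
# ---------------------------------------------------------------------------


def read_events(path: str | Path) -> EventList:
    """Read the native annotation table (TSV: onset_s, duration_s, label)."""
    path = Path(path)
    if not path.exists():
        raise PsgIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "label"}
    if not required <= set(df.columns):
        raise PsgIOError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return EventList(
        (row.onset_s, row.duration_s, row.label) for row in df.itertuples()
    )


def write_events(events: EventList, path: str | Path) -> None:
    df = pd.DataFrame(
        [(o, d, lab) for o, d, lab in events],
        columns=["onset_s", "duration_s", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    lines = Path(path).read_text().split()
    return Hypnogram(lines)


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    Path(path).write_text("\n".join(h.stages) + "\n")


def write_metadata_table(
    metas: Mapping[str, RecordingMeta], path: str | Path
) -> None:
    """Write a cohort metadata table: one row per recording id."""
    rows = []
    for rid, m in metas.items():
        rows.append(
            {
                "record_id": rid,
                "age": m.age,
                "sex": m.sex,
                "diagnosis_groups": ";".join(sorted(m.diagnosis_groups)),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata_table(path: str | Path) -> dict[str, RecordingMeta]:
    df = pd.read_csv(path, dtype={"record_id": str})
    out: dict[str, RecordingMeta] = {}
    for row in df.itertuples():
        groups = row.diagnosis_groups
        groups = (
            frozenset(g for g in str(groups).split(";") if g)
            if isinstance(groups, str) and groups
            else frozenset()
        )
        age = None if pd.isna(row.age) else float(row.age)
        sex = None if (not isinstance(row.sex, str)) else row.sex
        out[row.record_id] = RecordingMeta(age=age, sex=sex, diagnosis_groups=groups)
    return out


# ---------------------------------------------------------------------------
# record selection
# ---------------------------------------------------------------------------


def eligible_record(
    r: Recording,
    min_duration_s: float = 18000.0,
    min_eeg_rate: float = 200.0,
) -> bool:
    """Record-selection filter for overnight arousal scoring.

    A record qualifies when it is a plausible full night (at least 5 h by
    default) and every EEG channel is sampled fast enough (>= 200 Hz by
    default, the AASM-recommended floor) to resolve the frequency shifts
    that define arousals.
    """
    if r.duration_s < min_duration_s:
        return False
    for name in r.roles.get("EEG", []):
        if r.sample_rate[name] < min_eeg_rate:
            return False
    return True
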