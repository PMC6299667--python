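"""Reading EEG recordings and CAP event annotations; per-second label series.

Time convention used throughout the package: 0-based seconds, half-open
epochs [t, t+1).  Class codes: 0 = B (background), 1 = A1, 2 = A2, 3 = A3.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CLASS_NAMES = ("B", "A1", "A2", "A3")
SUBTYPE_CODES = {"A1": 1, "A2": 2, "A3": 3}

#: accepted spellings of the target channel, lower-cased and stripped of separators
_CHANNEL_SEPARATORS = re.compile(r"[-_\s]")


def _canon_channel(name: str) -> str:
    return _CHANNEL_SEPARATORS.sub("", name).lower()


class ChannelNotFoundError(KeyError):
    """Requested EEG channel is absent from the file."""


@dataclass
class EegRecording:
    """Single-channel EEG signal in microvolts.

    Parameters
    ----------
    samples : ndarray
        The signal x[n] in µV.
    fs : float
        Sampling rate in Hz (the source recordings range from 128 to 512 Hz).
    subject_id : str
    channel : str
        Channel label, expected "C4-A1".
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    channel: str = "C4-A1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs < 128:
            raise ValueError(f"sampling rate must be >= 128 Hz, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.fs

    @property
    def n_seconds(self) -> int:
        """Number of whole 1 s epochs."""
        return int(len(self.samples) // self.fs)


@dataclass(frozen=True)
class CapEvent:
    """One scored A-phase: onset and duration in seconds, subtype in {A1, A2, A3}."""

    onset: float
    duration: float
    subtype: str

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.subtype not in SUBTYPE_CODES:
            raise ValueError(f"unknown A-phase subtype {self.subtype!r}")
        if not (2.0 <= self.duration <= 60.0):
            warnings.warn(
                f"A-phase duration {self.duration} s outside the scored range [2, 60] s",
                stacklevel=2,
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def code(self) -> int:
        return SUBTYPE_CODES[self.subtype]


@dataclass
class LabelSeries:
    """Per-second class labels at 1 Hz; values in {0=B, 1=A1, 2=A2, 3=A3}."""

    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        bad = set(np.unique(self.labels)) - {0, 1, 2, 3}
        if bad:
            raise ValueError(f"labels outside {{0,1,2,3}}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def binary(self) -> np.ndarray:
        """A-vs-B collapse: 1 for any A subtype, 0 for background."""
        return (self.labels > 0).astype(int)


def read_recording(path, channel: str = "C4-A1") -> EegRecording:
    """Read one EEG channel from an EDF file.

    Accepts dialect variants of the channel label ("C4-A1", "C4A1",
    "C4_A1", with or without an "EEG " prefix).  Returns the signal in µV
    at its native sampling rate.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    except Exception as exc:  # pragma: no cover - depends on broken input
        raise OSError(f"cannot read EDF file {path}: {exc}") from exc

    want = _canon_channel(channel)
    match = None
    for name in raw.ch_names:
        canon = _canon_channel(name)
        if canon == want or canon == "eeg" + want:
            match = name
            break
    if match is None:
        raise ChannelNotFoundError(
            f"channel {channel!r} not found in {path.name}; available: {raw.ch_names}"
        )
    raw.load_data(verbose="error")
    data = raw.get_data(picks=[match])[0] * 1e6  # MNE returns volts
    return EegRecording(samples=data, fs=float(raw.info["sfreq"]),
                        subject_id=path.stem, channel=channel)


_ANN_HEADER = "onset_s\tduration_s\tsubtype"


def read_cap_annotations(path) -> list[CapEvent]:
    """Read CAP A-phase events from the canonical 3-column TSV format.

    The format is a strict TSV with header ``onset_s<TAB>duration_s<TAB>subtype``
    and subtype in {A1, A2, A3}.  Events are returned sorted chronologically.
    Durations outside [2, 60] s raise a warning but the event is kept.
    """
    events: list[CapEvent] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return events
    start = 1 if lines[0].strip().lower().startswith("onset") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}")
        try:
            onset = float(parts[0])
            dur = float(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric onset/duration") from exc
        subtype = parts[2].strip()
        if subtype not in SUBTYPE_CODES:
            raise ValueError(f"{path}:{lineno}: unknown subtype {subtype!r}")
        events.append(CapEvent(onset, dur, subtype))
    return sorted(events, key=lambda e: (e.onset, e.end))


def write_cap_annotations(events, path) -> None:
    """Write events in the canonical TSV format (chronological order)."""
    with open(path, "w") as fh:
        fh.write(_ANN_HEADER + "\n")
        for ev in sorted(events, key=lambda e: (e.onset, e.end)):
            fh.write(f"{ev.onset:g}\t{ev.duration:g}\t{ev.subtype}\n")


def read_physionet_annotations(path) -> list[CapEvent]:
    """Best-effort importer for free-text Physionet CAP scoring exports.

    Scans each line for a subtype token (A1/A2/A3 or "MCAP-A1" style) plus
    numeric position/duration fields; rows without a recognizable A-phase
    are skipped silently.  Prefer the canonical TSV for anything that must
    be deterministic.
    """
    token = re.compile(r"\bA([123])\b")
    events: list[CapEvent] = []
    with open(path) as fh:
        for line in fh:
            m = token.search(line.replace("MCAP-", ""))
            if not m:
                continue
            nums = re.findall(r"\b\d+(?:\.\d+)?\b", line.replace(f"A{m.group(1)}", " "))
            if len(nums) < 2:
                continue
            onset, dur = float(nums[0]), float(nums[-1])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    events.append(CapEvent(onset, dur, f"A{m.group(1)}"))
            except ValueError:
                continue
    return sorted(events, key=lambda e: (e.onset, e.end))


def build_second_labels(events, duration: float, subject_id: str = "") -> LabelSeries:
    """Discretize A-phase events to 1 Hz labels.

    Second t takes the label of the event covering the majority of
    [t, t+1); an exact half-second tie goes to the A-phase (the minority
    class must not be eroded by boundary effects).  Where events overlap,
    the later-onset event wins.  Events extending past the recording end
    are truncated with a warning.
    """
    n = int(np.floor(duration))
    labels = np.zeros(n, dtype=int)
    if not events:
        return LabelSeries(labels, subject_id)

    # paint intervals in onset order so later events overwrite earlier ones
    painted: list[list] = []  # [start, end, code]
    for ev in sorted(events, key=lambda e: e.onset):
        start, end = ev.onset, ev.end
        if end > duration:
            warnings.warn(
                f"event at {ev.onset} s extends past recording end ({duration} s); truncated",
                stacklevel=2,
            )
            end = duration
        if end <= start:
            continue
        clipped: list[list] = []
        for seg in painted:
            s, e, c = seg
            if e <= start or s >= end:
                clipped.append(seg)
            else:  # split around the new event
                if s < start:
                    clipped.append([s, start, c])
                if e > end:
                    clipped.append([end, e, c])
        clipped.append([start, end, ev.code])
        painted = clipped

    # per-second coverage, iterated in paint order so later-onset wins ties
    coverage = np.zeros((n, 4))
    order = np.full((n, 4), -1)  # paint sequence number, for tie-breaks
    for rank, (s, e, c) in enumerate(painted):
        for t in range(int(np.floor(s)), min(n, int(np.ceil(e)))):
            ov = min(e, t + 1) - max(s, t)
            if ov > 0:
                coverage[t, c] += ov
                order[t, c] = rank

    a_cov = coverage[:, 1:].sum(axis=1)
    for t in np.nonzero(a_cov >= 0.5 - 1e-12)[0]:  # A tie beats B
        cov = coverage[t, 1:]
        best = np.nonzero(cov >= cov.max() - 1e-12)[0]
        if len(best) > 1:  # tie among subtypes: later paint order wins
            best = [best[np.argmax(order[t, 1:][best])]]
        labels[t] = best[0] + 1
    return LabelSeries(labels, subject_id)


# ---------------------------------------------------------------------------
# Minimal EDF writer (16-bit, 1-second data records).  Only what the synth
# CLI and the round-trip tests need; reading always goes through MNE.
# ---------------------------------------------------------------------------

def write_edf(recording: EegRecording, path) -> None:
    """Write a single-channel recording as a plain EDF file."""
    x = recording.samples
    fs = int(round(recording.fs))
    if fs != recording.fs:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = len(x) // fs
    x = x[: n_rec * fs]

    phys_max = float(max(np.max(np.abs(x)), 1.0)) * 1.0001
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),                              # version
        pad(recording.subject_id or "X", 80),     # patient id
        pad("capscore", 80),                      # recording id
        pad("01.01.00", 8), pad("00.00.00", 8),   # start date/time
        pad(str(256 + 256), 8),                   # header bytes (1 signal)
        pad("", 44),                              # reserved
        pad(str(n_rec), 8),                       # number of data records
        pad("1", 8),                              # record duration (s)
        pad("1", 4),                              # number of signals
        # per-signal fields
        pad(recording.channel, 16),
        pad("AgAgCl electrode", 80),
        pad("uV", 8),
        pad(f"{phys_min:.1f}", 8), pad(f"{phys_max:.1f}", 8),
        pad(str(dig_min), 8), pad(str(dig_max), 8),
        pad("", 80),                              # prefiltering
        pad(str(fs), 8),                          # samples per record
        pad("", 32),                              # reserved
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def write_labels_tsv(series: LabelSeries, path) -> None:
    """Write per-second labels as a 2-column TSV (second, label name)."""
    with open(path, "w") as fh:
        fh.write("second\tlabel\n")
        for t, code in enumerate(series.labels):
            fh.write(f"{t}\t{CLASS_NAMES[code]}\n")
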