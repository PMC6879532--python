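"""EEG recording containers, EDF/CSV input-output and mastoid re-referencing.

Recordings are held as a channels x time float array in microvolts.  EDF
(16-bit European Data Format) is the interchange format: reading goes through
MNE-Python; writing uses a minimal single-record-per-second EDF encoder with
physical range +/-3276.8 uV, i.e. 0.1 uV amplitude resolution.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MASTOID_CHANNELS, TASKS

EDF_PHYS_MAX = 3276.7
EDF_PHYS_MIN = -3276.8
EDF_DIG_MAX = 32767
EDF_DIG_MIN = -32768
#: One EDF digital unit in microvolts.
EDF_RESOLUTION = (EDF_PHYS_MAX - EDF_PHYS_MIN) / (EDF_DIG_MAX - EDF_DIG_MIN)


class ChannelMissingError(KeyError):
    """A required channel label is absent from the recording."""


class ReferenceError_(ValueError):
    """Invalid re-referencing request (mastoids absent or already applied)."""


@dataclass
class RawRecording:
    """Multichannel EEG samples in microvolts.

    ``reference`` is ``"raw"`` as acquired, or ``"linked-mastoid"`` once each
    scalp channel has had the mastoid average subtracted.
    """

    samples: np.ndarray  # (n_channels, n_samples), uV
    channel_labels: tuple[str, ...]
    sampling_rate: float
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("channel count does not match label count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ChannelMissingError(
                f"channel {label!r} not present (have {list(self.channel_labels)})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def copy_with(self, samples: np.ndarray, **kwargs) -> "RawRecording":
        return replace(self, samples=samples, **kwargs)


@dataclass
class MarkerStream:
    """Task interval markers: (task_label, start_sample, end_sample).

    Sample indices are 0-based and half-open, ``[start, end)``.
    """

    entries: list[tuple[str, int, int]] = field(default_factory=list)

    def validate(self, n_samples: int, known_tasks: tuple[str, ...] = TASKS) -> None:
        prev_end = None
        for task, start, end in sorted(self.entries, key=lambda e: e[1]):
            if task not in known_tasks:
                raise ValueError(f"unknown task label {task!r}")
            if not (0 <= start < end <= n_samples):
                raise ValueError(f"marker {task}: [{start}, {end}) outside recording")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"marker {task} overlaps the previous interval")
            prev_end = end

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["task", "start_sample", "end_sample"])
            for task, start, end in self.entries:
                writer.writerow([task, start, end])

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerStream":
        df = pd.read_csv(path)
        if df.empty:
            return cls(entries=[])
        entries = [
            (str(row.task), int(row.start_sample), int(row.end_sample))
            for row in df.itertuples()
        ]
        return cls(entries=entries)


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: RawRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF, one 1-second data record per second.

    The recording is zero-padded to a whole number of seconds.  Samples
    outside the +/-3276.8 uV physical range are clipped.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = len(recording.channel_labels)
    n = recording.n_samples
    n_records = int(np.ceil(n / fs)) if n else 0
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n] = recording.samples

    scale = (EDF_DIG_MAX - EDF_DIG_MIN) / (EDF_PHYS_MAX - EDF_PHYS_MIN)
    digital = np.clip(
        np.round((padded - EDF_PHYS_MIN) * scale) + EDF_DIG_MIN, EDF_DIG_MIN, EDF_DIG_MAX
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field(f"Startdate 01-JAN-2000 X X {Path(path).stem[:20]}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 * (n_ch + 1), 8),
            _edf_field("", 44),
            _edf_field(n_records, 8),
            _edf_field(1, 8),  # record duration, seconds
            _edf_field(n_ch, 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(_edf_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(EDF_PHYS_MIN, 8) for _ in range(n_ch)),
            b"".join(_edf_field(EDF_PHYS_MAX, 8) for _ in range(n_ch)),
            b"".join(_edf_field(EDF_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_edf_field(EDF_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(fs, 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # data records: per record, channel-major blocks of fs samples
        for rec_i in range(n_records):
            block = digital[:, rec_i * fs : (rec_i + 1) * fs]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (microvolts)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import mne  # deferred: heavy import

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # volts -> microvolts
    return RawRecording(
        samples=samples,
        channel_labels=tuple(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        reference="raw",
    )


def rereference_linked_mastoids(recording: RawRecording) -> RawRecording:
    """Subtract the mastoid average from every scalp channel.

    The mastoid channels are dropped from the output and the reference flag
    is set; calling this twice is an error rather than a silent re-apply.
    """
    if recording.reference != "raw":
        raise ReferenceError_("recording is already re-referenced")
    labels = recording.channel_labels
    missing = [m for m in MASTOID_CHANNELS if m not in labels]
    if missing:
        raise ReferenceError_(f"mastoid channels absent: {missing}")
    m_idx = [labels.index(m) for m in MASTOID_CHANNELS]
    scalp_idx = [i for i in range(len(labels)) if i not in m_idx]
    ref = recording.samples[m_idx].mean(axis=0)
    samples = recording.samples[scalp_idx] - ref
    return RawRecording(
        samples=samples,
        channel_labels=tuple(labels[i] for i in scalp_idx),
        sampling_rate=recording.sampling_rate,
        reference="linked-mastoid",
    )


def write_manifest(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=["participant_id", "group", "edf_path", "markers_path"]).to_csv(
        path, index=False
    )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"participant_id", "group", "edf_path", "markers_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(df.columns))}")
    return df
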