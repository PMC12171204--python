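"""Reading sensor column logs and segmenting recordings into labeled windows.

The canonical in-memory object is :class:`MultimodalRecording`: a set of
synchronized, equally sampled channels (ECG, EMG, tri-axial accelerometer,
...) with one integer activity label per sample and a subject identifier.
Recordings are segmented into fixed-length :class:`SignalWindow` objects;
a window inherits the majority label of its samples and is discarded when
the label mixture falls below a purity threshold.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

VALID_ROLES = {"ecg", "emg", "acc_x", "acc_y", "acc_z", "other"}


@dataclass
class ColumnSchema:
    """Declarative description of a delimited sensor log.

    Parameters
    ----------
    columns
        Ordered channel names, one per data column (label column excluded).
    channel_roles
        Maps each channel name to a role in ``{ecg, emg, acc_x, acc_y,
        acc_z, other}``.
    sampling_rate_hz
        Sampling rate of every channel; never inferred from the file.
    label_column
        Zero-based index of the label column. ``-1`` (default) means the
        last column.
    delimiter
        ``None`` splits on any whitespace; otherwise a literal delimiter
        such as ``","``.
    subject_id
        Subject identifier attached to the resulting recording.
    """

    columns: list[str]
    channel_roles: dict[str, str] = field(default_factory=dict)
    sampling_rate_hz: float = 50.0
    label_column: int = -1
    delimiter: str | None = None
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("channel names must be unique")
        for name, role in self.channel_roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for channel {name!r}")


@dataclass
class MultimodalRecording:
    """Synchronized multichannel samples with per-sample labels."""

    subject_id: str
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    labels: np.ndarray
    channel_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        lengths = {name: len(series) for name, series in self.channels.items()}
        n = len(self.labels)
        if n < 1:
            raise ValueError("recording must contain at least one sample")
        bad = {k: v for k, v in lengths.items() if v != n}
        if bad:
            raise ValueError(f"channel/label length mismatch: labels={n}, {bad}")
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    def role_channels(self, *roles: str) -> dict[str, np.ndarray]:
        """Channels whose declared role is in ``roles``, in channel order."""
        return {
            name: series
            for name, series in self.channels.items()
            if self.channel_roles.get(name) in roles
        }


@dataclass
class SignalWindow:
    """One fixed-length segment of a recording with a resolved label."""

    subject_id: str
    start_index: int
    length: int
    channels: dict[str, np.ndarray]
    label: int
    label_purity: float
    sampling_rate_hz: float
    channel_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("window length must be positive")
        for name, series in self.channels.items():
            if len(series) != self.length:
                raise ValueError(f"channel {name!r} length != window length")


def read_column_log(path: str | Path, schema: ColumnSchema) -> MultimodalRecording:
    """Parse a delimited sensor log into a :class:`MultimodalRecording`.

    One row per sample; blank lines are skipped; row order is preserved.
    Non-finite values (NaN/Inf) and non-numeric cells are rejected with the
    offending line number; so are rows with a wrong column count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")

    n_cols = len(schema.columns) + 1
    label_col = schema.label_column if schema.label_column >= 0 else n_cols - 1
    data_cols = [c for c in range(n_cols) if c != label_col]

    rows: list[list[float]] = []
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split(schema.delimiter) if schema.delimiter else line.split()
            if not parts or (len(parts) == 1 and not parts[0].strip()):
                continue
            if len(parts) != n_cols:
                raise ValueError(
                    f"line {lineno}: expected {n_cols} columns, found {len(parts)}"
                )
            try:
                values = [float(parts[c]) for c in data_cols]
                label = float(parts[label_col])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric cell ({exc})") from None
            if not all(np.isfinite(v) for v in values) or not np.isfinite(label):
                raise ValueError(f"line {lineno}: non-finite value")
            if label != int(label):
                raise ValueError(f"line {lineno}: non-integer label {label}")
            rows.append(values)
            labels.append(int(label))

    if not rows:
        raise ValueError(f"empty input: {path}")

    arr = np.asarray(rows, dtype=np.float64)
    channels = {name: arr[:, i].copy() for i, name in enumerate(schema.columns)}
    return MultimodalRecording(
        subject_id=schema.subject_id,
        sampling_rate_hz=schema.sampling_rate_hz,
        channels=channels,
        labels=np.asarray(labels, dtype=np.int64),
        channel_roles=dict(schema.channel_roles),
    )


def write_column_log(recording: MultimodalRecording, path: str | Path,
                     delimiter: str = " ", fmt: str = "%.6f") -> None:
    """Write a recording in the same delimited layout (label column last)."""
    path = Path(path)
    names = list(recording.channels)
    with open(path, "w") as fh:
        for i in range(recording.n_samples):
            cells = [fmt % recording.channels[name][i] for name in names]
            cells.append(str(int(recording.labels[i])))
            fh.write(delimiter.join(cells) + "\n")


def resolve_label(label_slice: np.ndarray, purity_threshold: float) -> tuple[int, float] | None:
    """Majority label of a window slice, or ``None`` if below purity.

    Purity is the majority fraction; ties break toward the smallest label
    value. Rejection is a value (``None``), never an exception.
    """
    label_slice = np.asarray(label_slice)
    if label_slice.size == 0:
        raise ValueError("empty label slice")
    counts = Counter(int(v) for v in label_slice)
    best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    purity = best[1] / label_slice.size
    if purity < purity_threshold:
        return None
    return best[0], purity


def segment(
    recording: MultimodalRecording,
    window_length_s: float = 5.0,
    overlap_fraction: float = 0.5,
    purity_threshold: float = 1.0,
    drop_labels: tuple[int, ...] = (),
) -> list[SignalWindow]:
    """Cut a recording into fixed-length, possibly overlapping windows.

    Stride is ``L * (1 - overlap)`` samples (floored, minimum 1); the
    trailing partial window is discarded. Windows whose resolved label is
    in ``drop_labels`` or whose purity falls below ``purity_threshold``
    are omitted.
    """
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    length = int(round(window_length_s * recording.sampling_rate_hz))
    if length < 2:
        raise ValueError("window must span at least 2 samples")
    n = recording.n_samples
    if length > n:
        warnings.warn(
            f"window ({length} samples) longer than recording ({n}); no windows",
            stacklevel=2,
        )
        return []
    stride = max(1, int(length * (1.0 - overlap_fraction)))
    windows: list[SignalWindow] = []
    for start in range(0, n - length + 1, stride):
        resolved = resolve_label(recording.labels[start:start + length], purity_threshold)
        if resolved is None:
            continue
        label, purity = resolved
        if label in drop_labels:
            continue
        windows.append(
            SignalWindow(
                subject_id=recording.subject_id,
                start_index=start,
                length=length,
                channels={
                    name: series[start:start + length]
                    for name, series in recording.channels.items()
                },
                label=label,
                label_purity=purity,
                sampling_rate_hz=recording.sampling_rate_hz,
                channel_roles=dict(recording.channel_roles),
            )
        )
    return windows
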