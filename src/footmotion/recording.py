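"""Data model and delimited-text I/O for 6-axis inertial recordings.

An :class:`IMURecording` holds a synchronously sampled stream from an
ankle-worn MEMS unit: three accelerometer channels in units of g and three
gyroscope channels in deg/s, at a fixed sample rate (100 Hz for the target
hardware).  Recordings are stored as plain CSV with a fixed column order
``t, ax, ay, az, gx, gy, gz``; leading ``#`` lines carry unit metadata.

Labels are per performed action, not per sample, so they live in a JSON
sidecar keyed by ``(recording_id, segment_index)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MOTIONS",
    "SKILLS",
    "IMURecording",
    "ActionLabel",
    "LabelSet",
    "ParseError",
    "ValidationError",
    "read_recording",
    "write_recording",
]

MOTIONS = ("passing", "shooting")
SKILLS = ("elite", "amateur")

#: fixed CSV column order
COLUMNS = ("t", "ax", "ay", "az", "gx", "gy", "gz")

_TIME_TOL = 1e-6  # allowed deviation of timestamp spacing from 1/sample_rate, s


class ValidationError(ValueError):
    """A recording, label set or configuration violates its invariants."""


class ParseError(ValueError):
    """A delimited-text file could not be parsed; the message names the line."""


@dataclass
class IMURecording:
    """A validated 6-channel inertial stream.

    Parameters
    ----------
    sample_rate:
        Sampling frequency in Hz; must be positive.
    timestamps:
        Per-sample times in seconds, strictly increasing with spacing equal
        to ``1/sample_rate`` within 1e-6 s.
    accel:
        ``(n, 3)`` array of (ax, ay, az) in g.
    gyro:
        ``(n, 3)`` array of (gx, gy, gz) in deg/s.
    subject_id:
        Opaque subject tag.
    metadata:
        Free-form key/value tags.
    """

    sample_rate: float
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    subject_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if not self.sample_rate > 0:
            raise ValidationError(f"sample_rate must be positive, got {self.sample_rate}")
        n = len(self.timestamps)
        if n < 1:
            raise ValidationError("recording must contain at least one sample")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValidationError(
                f"channel shape mismatch: {n} timestamps, accel {self.accel.shape}, "
                f"gyro {self.gyro.shape}"
            )
        if n > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sample_rate)) > _TIME_TOL:
                raise ValidationError(
                    "timestamp spacing deviates from 1/sample_rate by more than 1e-6 s"
                )

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def recording_id(self) -> str:
        return self.metadata.get("recording_id", self.subject_id)


@dataclass(frozen=True)
class ActionLabel:
    """Labels of one performed action: motion type and the subject's skill."""

    motion: str
    skill: str

    def __post_init__(self) -> None:
        if self.motion not in MOTIONS:
            raise ValidationError(f"unknown motion {self.motion!r}; expected one of {MOTIONS}")
        if self.skill not in SKILLS:
            raise ValidationError(f"unknown skill {self.skill!r}; expected one of {SKILLS}")


class LabelSet:
    """Mapping from (recording_id, segment_index) to an :class:`ActionLabel`."""

    def __init__(self, labels: Mapping[tuple[str, int], ActionLabel] | None = None):
        self._labels: dict[tuple[str, int], ActionLabel] = dict(labels or {})

    def add(self, recording_id: str, segment_index: int, motion: str, skill: str) -> None:
        self._labels[(recording_id, int(segment_index))] = ActionLabel(motion, skill)

    def get(self, recording_id: str, segment_index: int) -> ActionLabel | None:
        return self._labels.get((recording_id, int(segment_index)))

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self._labels))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LabelSet) and self._labels == other._labels

    def motions(self) -> set[str]:
        return {lab.motion for lab in self._labels.values()}

    def skills(self) -> set[str]:
        return {lab.skill for lab in self._labels.values()}

    def to_json(self, path: str | Path) -> Path:
        records = [
            {
                "recording_id": rid,
                "segment_index": idx,
                "motion": lab.motion,
                "skill": lab.skill,
            }
            for (rid, idx), lab in sorted(self._labels.items())
        ]
        path = Path(path)
        path.write_text(json.dumps(records, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelSet":
        records = json.loads(Path(path).read_text())
        labels = cls()
        for rec in records:
            labels.add(rec["recording_id"], rec["segment_index"], rec["motion"], rec["skill"])
        return labels


def read_recording(
    path: str | Path,
    sample_rate: float = 100.0,
    subject_id: str = "",
) -> IMURecording:
    """Read a recording from a CSV file with columns ``t, ax, ay, az, gx, gy, gz``.

    A six-column file (no time column) is accepted; timestamps are then
    synthesized as ``i / sample_rate``.  Malformed rows raise
    :class:`ParseError` naming the offending line; an empty file or
    non-monotone timestamps raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    # count leading comment lines so errors can cite physical line numbers
    n_comment = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break

    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file contains no data") from None
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None

    cols = [c.strip() for c in df.columns]
    has_time = cols == list(COLUMNS)
    if not has_time and cols != list(COLUMNS[1:]):
        raise ParseError(
            f"{path}: header must name columns {COLUMNS} (or the six channels "
            f"without time); got {tuple(cols)}"
        )
    if len(df) == 0:
        raise ValidationError(f"{path}: file contains a header but no samples")

    bad = df.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        line_no = row + n_comment + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: malformed row at line {line_no}")

    values = df.to_numpy(dtype=float)
    if has_time:
        t = values[:, 0]
        chans = values[:, 1:]
    else:
        t = np.arange(len(values)) / sample_rate
        chans = values
    return IMURecording(
        sample_rate=sample_rate,
        timestamps=t,
        accel=chans[:, :3],
        gyro=chans[:, 3:],
        subject_id=subject_id,
        metadata={"source": str(path), "recording_id": path.stem},
    )


def write_recording(recording: IMURecording, path: str | Path) -> Path:
    """Write a recording as CSV (fixed column order, unit comment header)."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([recording.timestamps, recording.accel, recording.gyro]),
        columns=list(COLUMNS),
    )
    with path.open("w") as fh:
        fh.write("# units: t in s, ax/ay/az in g, gx/gy/gz in deg/s\n")
        df.to_csv(fh, index=False, lineterminator="\n")
    return path
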