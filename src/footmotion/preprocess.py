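"""Denoising, action-peak detection and segmentation.

A kick or pass shows up as a short high-energy burst on the accelerometer.
The stages here are: 3-point moving-average smoothing of every channel, peak
detection on the Euclidean norm of the filtered acceleration, and cutting a
fixed-length window centred on each retained peak.  A plain sliding-window
tiler is provided for stream-style processing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .recording import IMURecording, ValidationError

__all__ = [
    "MotionSegment",
    "moving_average",
    "acceleration_magnitude",
    "detect_action_peaks",
    "segment_around_peaks",
    "sliding_windows",
]

logger = logging.getLogger(__name__)


@dataclass
class MotionSegment:
    """A fixed window of a recording centred on one detected action peak.

    ``accel`` and ``gyro`` are ``(W, 3)`` slices of the *raw* (unfiltered)
    recording; ``peak_index`` is the peak's sample index in the source
    recording and ``start_index`` the window's first sample there.
    """

    recording_id: str
    peak_index: int
    start_index: int
    accel: np.ndarray
    gyro: np.ndarray
    sample_rate: float
    motion: str | None = None
    skill: str | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.accel.shape != self.gyro.shape or self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError(
                f"segment channels must both be (W, 3); got accel {self.accel.shape}, "
                f"gyro {self.gyro.shape}"
            )
        if len(self.accel) < 1:
            raise ValidationError("segment must contain at least one sample")

    @property
    def window_length(self) -> int:
        return len(self.accel)


def moving_average(x: Sequence[float] | np.ndarray, width: int = 3) -> np.ndarray:
    """Centred moving-average filter with replicate (edge-value) padding.

    Output has the same length as the input; element *i* is the mean of the
    ``width`` samples centred at *i*.  ``width`` must be odd so the window is
    symmetric.
    """
    if width < 1 or width % 2 == 0:
        raise ValidationError(f"filter width must be a positive odd integer, got {width}")
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValidationError("cannot filter an empty sequence")
    if width == 1:
        return x.copy()
    return uniform_filter1d(x, size=width, mode="nearest")


def acceleration_magnitude(recording: IMURecording, filter_width: int = 3) -> np.ndarray:
    """Per-sample Euclidean norm of the moving-average-filtered acceleration."""
    filtered = np.column_stack(
        [moving_average(recording.accel[:, k], filter_width) for k in range(3)]
    )
    return np.linalg.norm(filtered, axis=1)


def detect_action_peaks(
    mag: Sequence[float] | np.ndarray,
    threshold: float,
    min_separation: int,
) -> list[int]:
    """Local maxima above ``threshold``, greedily thinned to ``min_separation``.

    When two candidates fall closer than ``min_separation`` samples the
    larger is kept; on an exact height tie the earlier index wins.  Returned
    indices are strictly increasing.
    """
    if not threshold > 0:
        raise ValidationError("threshold must be positive")
    if min_separation < 1:
        raise ValidationError("min_separation must be at least 1 sample")
    mag = np.asarray(mag, dtype=float)
    candidates, _ = find_peaks(mag, height=threshold)
    if len(candidates) == 0:
        return []
    # greedy selection: tallest first, earlier index on ties
    order = sorted(candidates, key=lambda i: (-mag[i], i))
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - j) >= min_separation for j in kept):
            kept.append(idx)
    return sorted(int(i) for i in kept)


def segment_around_peaks(
    recording: IMURecording,
    peaks: Sequence[int],
    window_length: float = 1.0,
) -> list[MotionSegment]:
    """Cut one ``window_length``-second window centred on each peak.

    Peaks whose full window would overrun either edge of the recording are
    dropped with a logged warning.  Channel values are raw slices of the
    recording (the smoothing used for detection is not applied here).
    """
    w = int(round(window_length * recording.sample_rate))
    if w < 3:
        raise ValidationError(
            f"window of {window_length} s at {recording.sample_rate} Hz is below 3 samples"
        )
    half = w // 2
    n = recording.n_samples
    segments: list[MotionSegment] = []
    for peak in peaks:
        start = int(peak) - half
        stop = start + w
        if start < 0 or stop > n:
            logger.warning(
                "dropping peak at sample %d of %s: %d-sample window does not fit",
                peak, recording.recording_id, w,
            )
            continue
        segments.append(
            MotionSegment(
                recording_id=recording.recording_id,
                peak_index=int(peak),
                start_index=start,
                accel=recording.accel[start:stop].copy(),
                gyro=recording.gyro[start:stop].copy(),
                sample_rate=recording.sample_rate,
                subject_id=recording.subject_id,
            )
        )
    return segments


def sliding_windows(x: Sequence[float] | np.ndarray, size: int, step: int) -> list[np.ndarray]:
    """Fixed-size windows starting at 0, step, 2*step, ...; partial tail dropped."""
    if size < 1 or step < 1:
        raise ValidationError("window size and step must be positive")
    x = np.asarray(x)
    n = x.shape[0]
    return [x[s : s + size] for s in range(0, n - size + 1, step)]
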