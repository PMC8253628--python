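"""Per-segment statistical features and the stacked feature matrix.

Each motion segment is summarized by 34 statistics: 25 computed from the raw
accelerometer/gyroscope channels and 9 from the attitude-angle trajectory
(pitch, roll, yaw in radians).  Estimator conventions: population (1/n)
moments throughout; skewness is the third standardized central moment,
defined as 0 for a (numerically) constant sequence; the interquartile range
uses linear-interpolation quantiles.

Feature names follow the field's channel shorthand: ``a``/``w`` for
acceleration and angular velocity, ``x/y/z`` for axes, ``p/r/y`` for pitch,
roll and yaw; prefixes ``R`` (RMS), ``D`` (variance), ``S`` (skewness),
``M`` (mean), ``Max/Min``, ``IQR`` and ``Std``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .attitude import AttitudeSeries
from .preprocess import MotionSegment
from .recording import ValidationError

__all__ = [
    "FEATURE_NAMES",
    "ATTITUDE_FEATURES",
    "rms",
    "variance",
    "skewness",
    "iqr",
    "std",
    "maximum",
    "minimum",
    "mean",
    "extract_features",
    "build_feature_matrix",
]

#: fixed column order of the feature matrix
FEATURE_NAMES = (
    "R_ay", "R_wx", "R_wy", "R_wz",
    "D_ax", "D_ay", "D_wy",
    "Max_ax", "Max_ay", "Min_ay", "Min_wy",
    "S_ax", "S_ay", "S_az", "S_wx", "S_wy", "S_wz",
    "IQR_ax", "IQR_ay", "IQR_az", "IQR_wx", "IQR_wy", "IQR_wz",
    "Std_ax", "Std_wy",
    "M_p", "M_r", "M_y",
    "R_p", "R_r", "R_y",
    "Std_p", "Std_r", "Std_y",
)

#: the attitude-trajectory columns (used for the with/without-angle ablation)
ATTITUDE_FEATURES = ("M_p", "M_r", "M_y", "R_p", "R_r", "R_y", "Std_p", "Std_r", "Std_y")


def _as_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("statistic of an empty sequence is undefined")
    return x.ravel()


def mean(x) -> float:
    return float(np.mean(_as_array(x)))


def rms(x) -> float:
    """Root mean square: sqrt of the mean of squares."""
    x = _as_array(x)
    return float(np.sqrt(np.mean(x * x)))


def variance(x) -> float:
    """Population (1/n) variance."""
    return float(np.var(_as_array(x)))


def std(x) -> float:
    """Population (1/n) standard deviation."""
    return float(np.std(_as_array(x)))


def maximum(x) -> float:
    return float(np.max(_as_array(x)))


def minimum(x) -> float:
    return float(np.min(_as_array(x)))


def skewness(x) -> float:
    """Third standardized central moment m3 / m2^(3/2); 0 for a constant."""
    x = _as_array(x)
    mu = np.mean(x)
    d = x - mu
    m2 = np.mean(d * d)
    # a constant sequence can leave rounding residue of order eps^2 in m2;
    # treat anything that small (relative to the signal level) as degenerate
    if m2 == 0.0 or np.sqrt(m2) < 1e-12 * (abs(mu) + 1.0):
        return 0.0
    m3 = np.mean(d ** 3)
    return float(m3 / m2 ** 1.5)


def iqr(x) -> float:
    """Interquartile range Q3 - Q1 with linear-interpolation quantiles."""
    x = _as_array(x)
    q1, q3 = np.percentile(x, [25.0, 75.0], method="linear")
    return float(q3 - q1)


def extract_features(segment: MotionSegment, attitude: AttitudeSeries) -> pd.Series:
    """The 34-entry feature vector of one segment, indexed by FEATURE_NAMES."""
    if len(attitude) != segment.window_length:
        raise ValidationError(
            f"attitude length {len(attitude)} does not match segment window "
            f"{segment.window_length}"
        )
    ax, ay, az = segment.accel.T
    wx, wy, wz = segment.gyro.T
    p, r, y = attitude.pitch, attitude.roll, attitude.yaw
    values = {
        "R_ay": rms(ay), "R_wx": rms(wx), "R_wy": rms(wy), "R_wz": rms(wz),
        "D_ax": variance(ax), "D_ay": variance(ay), "D_wy": variance(wy),
        "Max_ax": maximum(ax), "Max_ay": maximum(ay),
        "Min_ay": minimum(ay), "Min_wy": minimum(wy),
        "S_ax": skewness(ax), "S_ay": skewness(ay), "S_az": skewness(az),
        "S_wx": skewness(wx), "S_wy": skewness(wy), "S_wz": skewness(wz),
        "IQR_ax": iqr(ax), "IQR_ay": iqr(ay), "IQR_az": iqr(az),
        "IQR_wx": iqr(wx), "IQR_wy": iqr(wy), "IQR_wz": iqr(wz),
        "Std_ax": std(ax), "Std_wy": std(wy),
        "M_p": mean(p), "M_r": mean(r), "M_y": mean(y),
        "R_p": rms(p), "R_r": rms(r), "R_y": rms(y),
        "Std_p": std(p), "Std_r": std(r), "Std_y": std(y),
    }
    return pd.Series([values[name] for name in FEATURE_NAMES], index=list(FEATURE_NAMES))


def build_feature_matrix(
    pairs: Sequence[tuple[MotionSegment, AttitudeSeries]],
) -> pd.DataFrame:
    """Stack per-segment feature vectors into an (n, 34) DataFrame.

    Rows follow the input order; the index is ``recording_id#k`` where *k*
    numbers the segments of each recording in order of appearance.
    """
    if len(pairs) == 0:
        raise ValidationError("cannot build a feature matrix from zero segments")
    rows, ids = [], []
    counters: dict[str, int] = {}
    for segment, attitude in pairs:
        rows.append(extract_features(segment, attitude))
        k = counters.get(segment.recording_id, 0)
        counters[segment.recording_id] = k + 1
        ids.append(f"{segment.recording_id}#{k}")
    return pd.DataFrame(rows, index=ids)
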