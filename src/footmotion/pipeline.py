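"""End-to-end orchestration: recordings -> segments -> attitude -> features
-> (PCA) -> classifier -> evaluation report.

``run_pipeline`` evaluates one task ("motion": passing vs shooting, or
"skill": elite vs amateur, optionally restricted to one motion's segments).
``run_experiment`` reproduces the full study protocol: one motion-recognition
report plus one skill-assessment report per motion subset.  Everything is a
pure function of (config, inputs): the single ``config.rng_seed`` drives the
split and the CV fold assignment, so repeated runs give identical reports.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .attitude import compute_attitude
from .classify import (
    ClassifierModel,
    EvaluationReport,
    evaluate,
    fit_pca,
    split_dataset,
    train_classifier,
    transform_pca,
)
from .config import PipelineConfig
from .features import ATTITUDE_FEATURES, build_feature_matrix
from .preprocess import acceleration_magnitude, detect_action_peaks, segment_around_peaks
from .recording import IMURecording, LabelSet, ValidationError

__all__ = [
    "segment_recordings",
    "featurize",
    "run_pipeline",
    "run_experiment",
    "attitude_ablation_cv",
]

logger = logging.getLogger(__name__)


def segment_recordings(
    config: PipelineConfig,
    recordings: Sequence[IMURecording],
    labels: LabelSet | None = None,
):
    """Detect peaks in every recording and cut labeled segments.

    Segments inherit the label of their ordinal index within the recording;
    unlabeled segments keep ``motion``/``skill`` as None.
    """
    segments = []
    for rec in recordings:
        mag = acceleration_magnitude(rec, config.filter_width)
        min_sep = max(1, int(round(config.peak_min_separation * rec.sample_rate)))
        peaks = detect_action_peaks(mag, config.peak_threshold, min_sep)
        segs = segment_around_peaks(rec, peaks, config.window_length)
        for k, seg in enumerate(segs):
            if labels is not None:
                lab = labels.get(rec.recording_id, k)
                if lab is not None:
                    seg.motion, seg.skill = lab.motion, lab.skill
            segments.append(seg)
        logger.info("%s: %d peaks, %d segments", rec.recording_id, len(peaks), len(segs))
    return segments


def featurize(config: PipelineConfig, segments) -> pd.DataFrame:
    """Attitude trajectories plus the 34-feature matrix, with label columns."""
    if len(segments) == 0:
        raise ValidationError("no actions found: zero segments were detected")
    pairs = [(seg, compute_attitude(seg, config.euler_mode)) for seg in segments]
    F = build_feature_matrix(pairs)
    F["motion"] = [seg.motion for seg in segments]
    F["skill"] = [seg.skill for seg in segments]
    return F


def _task_labels(F: pd.DataFrame, task: str, motion: str | None) -> tuple[pd.DataFrame, np.ndarray]:
    if task not in ("motion", "skill"):
        raise ValidationError(f"unknown task {task!r}; expected 'motion' or 'skill'")
    sub = F if motion is None else F[F["motion"] == motion]
    sub = sub[sub[task].notna()]
    if len(sub) == 0:
        raise ValidationError("no labeled segments for this task")
    y = sub[task].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError(
            f"task {task!r} needs both classes present; got only {np.unique(y)}"
        )
    X = sub.drop(columns=["motion", "skill"])
    return X, y


def _fit_and_evaluate(
    config: PipelineConfig,
    X: pd.DataFrame,
    y: np.ndarray,
    algorithm: str,
) -> tuple[EvaluationReport, ClassifierModel]:
    train_idx, test_idx = split_dataset(X, y, config.split_fraction, config.rng_seed)
    Xtr, Xte = X.iloc[train_idx], X.iloc[test_idx]
    ytr, yte = y[train_idx], y[test_idx]

    if config.use_pca:
        pca = fit_pca(Xtr, config.pca_variance_kept)
        Ztr = transform_pca(pca, Xtr)
        Zte = transform_pca(pca, Xte)
    else:
        pca = None
        Ztr, Zte = Xtr.to_numpy(float), Xte.to_numpy(float)

    model = train_classifier(
        Ztr, ytr,
        algorithm=algorithm,
        grid=config.svm_grid if algorithm == "svm" else None,
        folds=config.cv_folds,
        seed=config.rng_seed,
        knn_neighbors=config.knn_neighbors,
        tree_min_samples_split=config.tree_min_samples_split,
        tree_max_depth=config.tree_max_depth,
    )
    report = evaluate(model, Zte, yte, seed=config.rng_seed)
    report.stage_counts = {
        "feature_rows": int(len(X)),
        "train_rows": int(len(train_idx)),
        "test_rows": int(len(test_idx)),
        "pca_components": int(pca.n_components) if pca is not None else 0,
    }
    return report, model


def run_pipeline(
    config: PipelineConfig,
    recordings: Sequence[IMURecording],
    labels: LabelSet,
    task: str = "motion",
    motion: str | None = None,
    algorithm: str = "svm",
) -> EvaluationReport:
    """The whole pipeline on raw recordings, returning one evaluation report.

    ``task="motion"`` classifies passing vs shooting; ``task="skill"``
    classifies elite vs amateur, optionally on one motion's segments only
    (``motion="passing"`` or ``"shooting"``).
    """
    segments = segment_recordings(config, recordings, labels)
    F = featurize(config, segments)
    X, y = _task_labels(F, task, motion)
    report, _ = _fit_and_evaluate(config, X, y, algorithm)
    report.stage_counts["segments"] = len(segments)
    report.stage_counts["recordings"] = len(recordings)
    return report


def run_experiment(
    config: PipelineConfig,
    recordings: Sequence[IMURecording],
    labels: LabelSet,
    algorithm: str = "svm",
) -> dict[str, EvaluationReport]:
    """Motion recognition plus per-motion skill assessment (shared features)."""
    segments = segment_recordings(config, recordings, labels)
    F = featurize(config, segments)
    reports: dict[str, EvaluationReport] = {}
    X, y = _task_labels(F, "motion", None)
    reports["motion"], _ = _fit_and_evaluate(config, X, y, algorithm)
    for motion in ("passing", "shooting"):
        X, y = _task_labels(F, "skill", motion)
        reports[f"skill_{motion}"], _ = _fit_and_evaluate(config, X, y, algorithm)
    for rep in reports.values():
        rep.stage_counts["segments"] = len(segments)
    return reports


def attitude_ablation_cv(
    F: pd.DataFrame,
    task: str = "skill",
    motion: str | None = None,
    config: PipelineConfig | None = None,
    C: float = 1.0,
    kernel: str = "linear",
) -> tuple[float, float]:
    """Mean CV accuracy of the SVM with and without the attitude features.

    Uses a fixed (C, kernel) configuration so the two runs differ only in
    the feature set.  Returns ``(accuracy_with, accuracy_without)``.
    """
    config = config or PipelineConfig()
    grid = {"C": [C], "gamma": [1e-4], "kernel": [kernel]}

    def cv_acc(X: pd.DataFrame, y: np.ndarray) -> float:
        if config.use_pca:
            pca = fit_pca(X, config.pca_variance_kept)
            Z = transform_pca(pca, X)
        else:  # features mix units; standardize so the margin is well-scaled
            V = X.to_numpy(float)
            sd = V.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (V - V.mean(axis=0)) / sd
        model = train_classifier(Z, y, "svm", grid, config.cv_folds, config.rng_seed)
        return model.cv_accuracy

    X, y = _task_labels(F, task, motion)
    with_att = cv_acc(X, y)
    without_att = cv_acc(X.drop(columns=list(ATTITUDE_FEATURES)), y)
    return with_att, without_att
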