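"""Run configuration for the full pipeline.

All tunables of every stage live in one :class:`PipelineConfig` so a run is a
pure function of (config, inputs).  The config round-trips losslessly through
YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .recording import ValidationError

__all__ = ["PipelineConfig", "DEFAULT_SVM_GRID"]

#: hyperparameter grid searched for the SVM: penalty C, kernel width gamma,
#: and kernel family.  gamma is inert for the linear kernel but still recorded.
DEFAULT_SVM_GRID = {
    "C": (1.0, 500.0, 1e3, 5e3, 1e4),
    "gamma": (1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3),
    "kernel": ("linear", "poly", "rbf", "sigmoid"),
}


@dataclass
class PipelineConfig:
    """Every stage's tunables, with defaults for the ankle-IMU pipeline.

    filter_width
        Moving-average width in samples (odd).  Default 3.
    peak_threshold
        Minimum filtered acceleration magnitude (g) for an action peak.
    peak_min_separation
        Minimum spacing between retained peaks, seconds.
    window_length
        Length of the segment cut around each peak, seconds.
    euler_mode
        ``"standard"`` (conventional aerospace Z-Y-X quaternion kinematics)
        or ``"paper_literal"`` (sign conventions preserved verbatim from the
        source formulas, for auditability).
    pca_variance_kept
        Fraction of variance the retained principal components must explain.
    use_pca
        Whether to compress features with PCA before classification.
    split_fraction
        Training fraction of the stratified train/test split.
    cv_folds
        Folds for the hyperparameter-selection cross-validation.
    rng_seed
        Single seed governing the split, fold assignment and any generation.
    """

    filter_width: int = 3
    peak_threshold: float = 1.2
    peak_min_separation: float = 1.0
    window_length: float = 1.0
    euler_mode: str = "standard"
    pca_variance_kept: float = 0.95
    use_pca: bool = True
    split_fraction: float = 0.8
    cv_folds: int = 3
    rng_seed: int = 0
    svm_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SVM_GRID.items()})
    knn_neighbors: int = 4
    tree_min_samples_split: int = 3
    tree_max_depth: int = 6

    def __post_init__(self) -> None:
        if self.filter_width < 1 or self.filter_width % 2 == 0:
            raise ValidationError(f"filter_width must be a positive odd integer, got {self.filter_width}")
        if not self.peak_threshold > 0:
            raise ValidationError("peak_threshold must be positive")
        if not self.peak_min_separation > 0:
            raise ValidationError("peak_min_separation must be positive")
        if not self.window_length > 0:
            raise ValidationError("window_length must be positive")
        if self.euler_mode not in ("standard", "paper_literal"):
            raise ValidationError(f"unknown euler_mode {self.euler_mode!r}")
        if not 0 < self.pca_variance_kept <= 1:
            raise ValidationError("pca_variance_kept must lie in (0, 1]")
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_file(self, path: str | Path) -> Path:
        """Write as YAML (or JSON when the suffix is .json)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)
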