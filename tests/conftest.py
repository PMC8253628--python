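import numpy as np
import pytest

import footmotion as fm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return fm.PipelineConfig(rng_seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """1 subject per skill, 6 actions per motion: 4 recordings, 24 actions."""
    return fm.generate_dataset(n_elite=1, n_amateur=1, actions_per_motion=6, seed=42)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    recordings, labels, _ = small_dataset
    cfg = fm.PipelineConfig(rng_seed=0)
    segments = fm.segment_recordings(cfg, recordings, labels)
    return fm.featurize(cfg, segments)


@pytest.fixture
def passing_template():
    return fm.default_templates()[("passing", "elite")]


@pytest.fixture
def shooting_template():
    return fm.default_templates()[("shooting", "elite")]
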