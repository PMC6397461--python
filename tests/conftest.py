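"""Shared fixtures: canonical synthetic studies, computed once per session."""

import numpy as np
import pytest

from cellvfa import pipeline, syndata


def desk_config(**overrides) -> pipeline.ExperimentConfig:
    """Desk-scale evaluation protocol used across the end-to-end tests."""
    base = dict(delta=4, L=10, R=10, scheme="fv", K=8,
                n_splits=5, n_train_per_class=10, seed=42)
    base.update(overrides)
    return pipeline.ExperimentConfig(**base)


@pytest.fixture(scope="session")
def two_class_study():
    """Binary normal/abnormal study: videos, features and labels."""
    videos, manifest = syndata.two_class_dataset()
    labels = manifest["label"].to_numpy()
    cfg = desk_config()
    feats = [pipeline.extract_video_features(v.frames, v.contours, cfg)
             for v in videos]
    return feats, labels, cfg


@pytest.fixture(scope="session")
def four_class_study():
    """Graded-activation study (4 classes, intermittent bouts)."""
    videos, manifest = syndata.four_class_dataset()
    labels = manifest["label"].to_numpy()
    cfg = desk_config(use_tpp=True)
    feats = [pipeline.extract_video_features(v.frames, v.contours, cfg)
             for v in videos]
    return feats, labels, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
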