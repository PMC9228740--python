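"""Shared fixtures: tiny scenes, a small trained segmenter, desk-scale models.

The expensive trained models are session-scoped so the end-to-end checks pay
the training cost once.
"""

from __future__ import annotations

import numpy as np
import pytest

import bloomspec as bs
from bloomspec import segnet


def constant_scene(values: dict[str, float], shape=(8, 8)) -> bs.MultispectralScene:
    """A scene whose every band is constant."""
    return bs.MultispectralScene(
        bands={b: np.full(shape, values.get(b, 0.2)) for b in bs.BAND_IDS}
    )


@pytest.fixture(scope="session")
def scheme() -> bs.ClassScheme:
    return bs.DEFAULT_SCHEME


@pytest.fixture(scope="session")
def small_trained() -> bs.TrainedSegmenter:
    """A quick low-capacity model for pipeline plumbing checks (64x64)."""
    cfg = bs.SceneConfig(height=64, width=64, seed=5)
    pairs = bs.generate_dataset(12, cfg, seed=5)
    data = segnet.prepare_training_data(pairs, input_size=64)
    seg_cfg = bs.SegmenterConfig(input_size=64, n_classes=4, epochs=15, seed=2)
    return bs.train(data, seg_cfg)


@pytest.fixture(scope="session")
def desk_trained() -> bs.TrainedSegmenter:
    """The desk-scale model: 32 default scenes at 96x96, fixed seed."""
    cfg = bs.SceneConfig(seed=7)
    pairs = bs.generate_dataset(32, cfg, seed=7)
    data = segnet.prepare_training_data(pairs, input_size=96)
    seg_cfg = bs.SegmenterConfig(input_size=96, n_classes=4, seed=3)
    return bs.train(data, seg_cfg)


@pytest.fixture(scope="session")
def heldout_scenes() -> list[tuple[bs.MultispectralScene, bs.LabelRaster]]:
    """Eight held-out default-preset scenes, disjoint seed stream."""
    return bs.generate_dataset(8, bs.SceneConfig(seed=7), seed=1007)
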