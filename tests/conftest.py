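"""Shared fixtures: synthetic corpora and the two trained networks.

Training happens once per session at pinned seeds; every test that needs a
trained model reuses these fixtures, which keeps the whole suite within a
desk-scale CPU budget.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sicklenet import classification as clf
from sicklenet import segmentation as seg
from sicklenet import synthetic as syn

SEG_DATA_SEED = 42
SEG_TRAIN_SEED = 0
CLF_DATA_SEED = 7
CLF_TRAIN_SEED = 0


@pytest.fixture(scope="session")
def seg_corpus():
    """200 labeled synthetic 150x150 tiles plus network-ready tensors."""
    scenes, _ = syn.make_dataset(
        200, {"height": 150, "width": 150, "n_cells": (1, 4)},
        seed=SEG_DATA_SEED)
    x, y = seg.prepare_training_data([s.image for s in scenes],
                                     [s.mask for s in scenes])
    return scenes, x, y


@pytest.fixture(scope="session")
def trained_segmenter(seg_corpus):
    """One segmenter trained on the 200-tile corpus (80/20 split)."""
    _, x, y = seg_corpus
    config = seg.SegModelConfig(seed=SEG_TRAIN_SEED)
    models, histories, splits = seg.train_segmenter(x, y, config, folds=1)
    return dict(model=models[0], history=histories[0], split=splits[0],
                x=x, y=y, config=config)


@pytest.fixture(scope="session")
def crop_corpus():
    """560 labeled synthetic 32x32 crops spanning all three categories."""
    crops, labels = syn.make_crop_dataset(560, seed=CLF_DATA_SEED)
    return crops, labels


@pytest.fixture(scope="session")
def trained_classifier(crop_corpus):
    """One small CNN trained on the crop corpus (80/20 split)."""
    crops, labels = crop_corpus
    config = clf.ClfModelConfig(seed=CLF_TRAIN_SEED)
    models, histories, splits = clf.train_classifier(crops, labels, config,
                                                     folds=1)
    return dict(model=models[0], history=histories[0], split=splits[0],
                crops=crops, labels=labels, config=config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
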