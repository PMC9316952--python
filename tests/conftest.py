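"""Shared fixtures: small synthetic imagery and a quickly trained model."""

import numpy as np
import pytest

from halocell import annotations as ann
from halocell import bcnn as bc
from halocell import synthetic as syn


@pytest.fixture(scope="session")
def small_config():
    return syn.SyntheticConfig(tile_width=256, tile_height=256, n_cells=6,
                               n_negatives=6, seed=42)


@pytest.fixture(scope="session")
def small_tile(small_config):
    tile, marks = syn.generate_tile(small_config)
    return tile, marks


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained, deliberately small bifocal net for shape/plumbing tests."""
    return bc.build_model(bc.BCNNConfig(channels=(8, 16), hidden=16, seed=0))


@pytest.fixture(scope="session")
def trained_small_model():
    """A small net trained briefly on an easy synthetic task.

    Used by tests that need actual discrimination (background tiles
    scoring low, positive rings scoring high); kept small so the whole
    fixture builds in well under a minute.
    """
    tiles, marks = [], []
    for i in range(3):
        cfg = syn.SyntheticConfig(tile_width=256, tile_height=256, n_cells=8,
                                  n_negatives=8, seed=200 + i,
                                  stain_intensity_range=(0.4, 0.7))
        tile, tile_marks = syn.generate_tile(cfg, case_id="fit",
                                             tile_id=f"tile{i}")
        tiles.append(tile)
        marks.extend(tile_marks)
    pairs = ann.build_training_set(tiles, marks, augment=True, n_variants=3,
                                   hard_negative_per_positive=2, seed=5)
    cfg = bc.BCNNConfig(channels=(8, 16), hidden=16, epochs=8,
                        learning_rate=0.002, lr_min=0.0005, seed=3)
    model = bc.build_model(cfg)
    bc.train(model, pairs, cfg)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
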