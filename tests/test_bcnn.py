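"""Bifocal classifier: probabilities, determinism, training, metrics."""

import numpy as np
import pytest

from halocell import bcnn as bc
from halocell.annotations import BifocalPatchPair


def _random_pairs(n, rng, balanced=True):
    pairs = []
    for i in range(n):
        label = "positive" if (i % 2 == 0 if balanced else True) else "negative"
        pairs.append(BifocalPatchPair(
            narrow=rng.random((32, 32, 3)), wide=rng.random((64, 64, 3)),
            centre=(32, 32), label=label))
    return pairs


def _separable_pairs(n, rng):
    """Positives carry a bright ring signature, negatives are flat noise."""
    pairs = []
    yy, xx = np.mgrid[:64, :64]
    ring = (np.hypot(xx - 32, yy - 32) > 10) & (np.hypot(xx - 32, yy - 32) < 16)
    for i in range(n):
        wide = rng.random((64, 64, 3)) * 0.2 + 0.7
        label = "negative"
        if i % 2 == 0:
            wide[ring] = [0.5, 0.35, 0.2] + rng.normal(0, 0.02, (ring.sum(), 3))
            label = "positive"
        pairs.append(BifocalPatchPair(narrow=wide[16:48, 16:48].copy(),
                                      wide=wide, centre=(32, 32), label=label))
    return pairs


class TestBuildAndForward:
    def test_forward_rows_are_probabilities(self, tiny_model, rng):
        narrow = rng.random((32, 32, 32, 3)).astype(np.float32)
        wide = rng.random((32, 64, 64, 3)).astype(np.float32)
        proba = tiny_model.predict_proba(narrow, wide)
        assert proba.shape == (32, 2)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((proba >= 0) & (proba <= 1))

    def test_same_seed_identical_initialisation(self):
        cfg = bc.BCNNConfig(channels=(8,), hidden=8, seed=7)
        a, b = bc.build_model(cfg), bc.build_model(cfg)
        assert all(np.array_equal(p.value, q.value)
                   for p, q in zip(a.params(), b.params()))

    def test_zero_images_give_finite_outputs(self, tiny_model):
        proba = tiny_model.predict_proba(np.zeros((4, 32, 32, 3), np.float32),
                                         np.zeros((4, 64, 64, 3), np.float32))
        assert np.all(np.isfinite(proba))

    def test_duplicated_pair_scores_identically(self, tiny_model, rng):
        pairs = _random_pairs(6, rng)
        scores = bc.predict_pairs(tiny_model, pairs + pairs)
        assert np.array_equal(scores[:6], scores[6:])

    def test_batch_size_does_not_change_scores(self, tiny_model, rng):
        pairs = _random_pairs(40, rng)
        s1 = bc.predict_pairs(tiny_model, pairs, batch_size=1)
        s256 = bc.predict_pairs(tiny_model, pairs, batch_size=256)
        assert np.allclose(s1, s256, atol=1e-6)

    def test_save_load_roundtrip(self, tiny_model, tmp_path, rng):
        tiny_model.save(tmp_path / "model")
        back = bc.BifocalNet.load(tmp_path / "model")
        pairs = _random_pairs(4, rng)
        assert np.array_equal(bc.predict_pairs(tiny_model, pairs),
                              bc.predict_pairs(back, pairs))


class TestTrain:
    def test_loss_decreases_on_learnable_data(self, rng):
        pairs = _separable_pairs(200, rng)
        cfg = bc.BCNNConfig(channels=(8,), hidden=8, epochs=5,
                            learning_rate=0.002, seed=0)
        model = bc.build_model(cfg)
        history = bc.train(model, pairs, cfg)
        assert history["loss"][-1] < history["loss"][0]

    def test_training_is_seed_deterministic(self, rng):
        pairs = _separable_pairs(60, rng)
        cfg = bc.BCNNConfig(channels=(4,), hidden=8, epochs=2, seed=5)
        runs = []
        for _ in range(2):
            model = bc.build_model(cfg)
            bc.train(model, pairs, cfg)
            runs.append([p.value.copy() for p in model.params()])
        assert all(np.array_equal(a, b) for a, b in zip(*runs))

    def test_single_class_training_set_rejected(self, rng):
        pairs = _random_pairs(10, rng, balanced=False)
        cfg = bc.BCNNConfig(channels=(4,), seed=0)
        with pytest.raises(ValueError, match="single class"):
            bc.train(bc.build_model(cfg), pairs, cfg)

    def test_empty_training_set_rejected(self):
        cfg = bc.BCNNConfig(channels=(4,), seed=0)
        with pytest.raises(ValueError, match="empty"):
            bc.train(bc.build_model(cfg), [], cfg)

    def test_trained_model_separates_synthetic_task(self, trained_small_model,
                                                    rng):
        # small-scale version of the learning property: the pinned recipe
        # must clearly separate rings from background on held-out pairs
        from halocell import annotations as ann
        from halocell import synthetic as syn
        cfg = syn.SyntheticConfig(tile_width=256, tile_height=256, n_cells=8,
                                  n_negatives=8, seed=990,
                                  stain_intensity_range=(0.4, 0.7))
        tile, marks = syn.generate_tile(cfg, case_id="holdout")
        pairs = ann.build_training_set([tile], marks)
        scores = bc.predict_pairs(trained_small_model, pairs)
        labels = np.array([1 if p.label == "positive" else 0 for p in pairs])
        report = bc.evaluate(scores, labels)
        assert report.auc > 0.9


class TestEvaluate:
    def test_perfect_scores(self):
        labels = np.array([0, 1] * 20)
        report = bc.evaluate(labels.astype(float), labels)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert report.f1 == 1.0

    def test_toy_confusion_matrix_closed_form(self):
        # TP=8, FP=1, FN=1, TN=10
        scores = np.array([1.0] * 8 + [1.0] + [0.0] + [0.0] * 10)
        labels = np.array([1] * 8 + [0] + [1] + [0] * 10)
        report = bc.evaluate(scores, labels)
        assert (report.tp, report.fp, report.fn, report.tn) == (8, 1, 1, 10)
        assert report.precision == pytest.approx(8 / 9)
        assert report.recall == pytest.approx(8 / 9)
        assert report.f1 == pytest.approx(8 / 9)
        assert report.specificity == pytest.approx(10 / 11)
        assert report.confusion_matrix().sum() == report.n == 20

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(123)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert bc.evaluate(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_metrics_invariant_under_permutation(self, rng):
        scores = rng.random(500)
        labels = rng.integers(0, 2, 500)
        perm = rng.permutation(500)
        a = bc.evaluate(scores, labels)
        b = bc.evaluate(scores[perm], labels[perm])
        assert (a.accuracy, a.precision, a.recall, a.f1, a.auc) == \
            (b.accuracy, b.precision, b.recall, b.f1, b.auc)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            bc.evaluate(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_f1_is_harmonic_mean(self, rng):
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        r = bc.evaluate(scores, labels)
        if r.precision + r.recall > 0:
            assert r.f1 == pytest.approx(
                2 * r.precision * r.recall / (r.precision + r.recall))
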