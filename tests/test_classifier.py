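"""Classifier contracts: softmax output, seeded construction, training
protocol (best-epoch selection, overfit capacity), prediction determinism
and occlusion saliency."""

import numpy as np
import pytest

import wsidriver as w
from wsidriver.classifier import (
    EpochStats,
    ModelConfig,
    TrainingLog,
    load_model,
    save_model,
)


@pytest.fixture(scope="module")
def small_model():
    return w.build_model(ModelConfig(seed=1))


def _random_tiles(n, seed=0):
    return np.random.default_rng(seed).integers(0, 256, size=(n, 512, 512, 3)).astype(np.uint8)


class TestBuild:
    def test_softmax_contract(self, small_model):
        probs = small_model.predict_proba(_random_tiles(3))
        assert probs.shape == (3, 2)
        assert np.all((probs >= 0) & (probs <= 1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_seeded_rebuild_identical(self):
        x = _random_tiles(2)
        a = w.build_model(ModelConfig(seed=4)).predict_proba(x)
        b = w.build_model(ModelConfig(seed=4)).predict_proba(x)
        assert np.array_equal(a, b)

    def test_small_variant_parameter_budget(self, small_model):
        assert small_model.n_parameters() < 1_000_000

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            ModelConfig(architecture_scale="huge")

    def test_full_variant_forward(self):
        model = w.build_model(ModelConfig(architecture_scale="full", seed=0))
        probs = model.predict_proba(_random_tiles(1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)


class TestTrainingLog:
    def test_best_epoch_is_argmin(self):
        log = TrainingLog(
            epochs=[
                EpochStats(1, 1.0, 0.9, 0.5),
                EpochStats(2, 0.8, 0.4, 0.7),
                EpochStats(3, 0.7, 0.6, 0.6),
            ]
        )
        assert log.best_epoch == 2

    def test_ties_resolve_to_first(self):
        log = TrainingLog(
            epochs=[EpochStats(1, 1.0, 0.5, 0.5), EpochStats(2, 0.9, 0.5, 0.5)]
        )
        assert log.best_epoch == 1


class TestTrain:
    def test_single_class_rejected_before_first_epoch(self):
        x = _random_tiles(4)
        y = np.zeros(4, dtype=int)
        model = w.build_model(ModelConfig(epochs=1, seed=0))
        with pytest.raises(ValueError, match="single class"):
            w.train(model, (x, y), (x, y))

    def test_overfits_separable_tiles(self, trained_small_model):
        """The small model has the capacity to drive training accuracy to
        ~1 on a fully separable tile set."""
        best, log, (x, y) = trained_small_model
        probs = best.predict_proba(x)
        assert (probs.argmax(axis=1) == y).mean() >= 0.99

    def test_validation_loss_improves_to_best_epoch(self, trained_small_model):
        _, log, _ = trained_small_model
        losses = [e.val_loss for e in log.epochs]
        assert losses[log.best_epoch - 1] < losses[0]

    def test_best_epoch_matches_serialized_log(self, trained_small_model):
        import json

        _, log, _ = trained_small_model
        data = json.loads(log.to_json())
        losses = [e["val_loss"] for e in data["epochs"]]
        assert data["best_epoch"] == int(np.argmin(losses)) + 1


class TestPredict:
    def test_inference_deterministic(self, trained_small_model):
        best, _, (x, _) = trained_small_model
        a = w.predict_tiles(best, x[:3], ["s"] * 3)
        b = w.predict_tiles(best, x[:3], ["s"] * 3)
        assert [t.p_ras for t in a] == [t.p_ras for t in b]
        assert all(0.0 <= t.p_ras <= 1.0 for t in a)
        assert a[0].p_braf == pytest.approx(1.0 - a[0].p_ras)

    def test_wrong_shape_names_offender(self, small_model):
        tiles = [np.zeros((512, 512, 3), np.uint8), np.zeros((256, 256, 3), np.uint8)]
        with pytest.raises(ValueError, match="tile bad"):
            w.predict_tiles(small_model, np.array(tiles, dtype=object), ["s", "s"], ["ok", "bad"])

    def test_generalizes_to_held_out_tiles(self, trained_small_model, separable_tiles):
        """Held-out tiles from the training slides are separated almost
        perfectly (tile-level AUC)."""
        best, _, _ = trained_small_model
        _, _, x_test, y_test = separable_tiles
        probs = best.predict_proba(x_test)[:, 1]
        auc, _, _ = w.roc_auc(probs, y_test, n_boot=0)
        assert auc >= 0.95

    def test_checkpoint_round_trip(self, trained_small_model, tmp_path):
        best, log, (x, _) = trained_small_model
        path = tmp_path / "model.npz"
        save_model(best, log, path)
        loaded = load_model(path)
        assert np.array_equal(loaded.predict_proba(x[:4]), best.predict_proba(x[:4]))


class TestActivationMap:
    def test_uniform_tile_near_flat(self, trained_small_model):
        best, _, _ = trained_small_model
        tile = np.full((512, 512, 3), 128, dtype=np.uint8)
        heat = w.activation_map(best, tile, occluder_size=128, stride=128)
        assert heat.max() - heat.min() < 0.1

    def test_heatmap_dimensions(self, small_model):
        tile = np.full((512, 512, 3), 128, dtype=np.uint8)
        for occ, stride in [(64, 64), (100, 64), (128, 96)]:
            heat = w.activation_map(small_model, tile, occ, stride)
            expected = int(np.ceil((512 - occ) / stride)) + 1
            assert heat.shape == (expected, expected)

    def test_oversized_occluder_rejected(self, small_model):
        with pytest.raises(ValueError, match="occluder"):
            w.activation_map(small_model, np.zeros((512, 512, 3), np.uint8), 600, 64)

    def test_saliency_concentrates_on_informative_quadrant(self, braf_slide):
        """A model trained on nuclear evidence (tissue-with-nuclei vs glass)
        loses confidence exactly where the occluder hides the nuclei, so
        top-decile saliency cells cluster in the one populated quadrant."""
        rng = np.random.default_rng(0)
        tissue = np.stack(
            [
                w.read_region(braf_slide[1], c)
                for c in list(w.enumerate_candidates(braf_slide[1]))[:8]
            ]
        )
        glass = rng.normal(250, 2, size=(8, 512, 512, 3)).clip(0, 255).astype(np.uint8)
        # positives: tissue confined to one random quadrant over glass
        quarter = glass.copy()
        for i in range(8):
            qy, qx = rng.integers(0, 2, size=2) * 256
            quarter[i, qy : qy + 256, qx : qx + 256] = tissue[i, :256, :256]
        x = np.concatenate([glass, quarter])
        y = np.array([0] * 8 + [1] * 8)
        cfg = ModelConfig(epochs=6, seed=2)
        model, _ = w.train(w.build_model(cfg), (x, y), (x, y), cfg)

        tile = rng.normal(250, 2, size=(512, 512, 3)).clip(0, 255).astype(np.uint8)
        tile[:256, :256] = tissue[0, :256, :256]
        probs = model.predict_proba(tile[None])[0]
        assert probs.argmax() == 1  # the quadrant carries the call
        heat = w.activation_map(model, tile, occluder_size=128, stride=64)
        n = heat.shape[0]
        top = heat >= np.quantile(heat, 0.9)
        in_quadrant = top[: n // 2 + 1, : n // 2 + 1].sum()
        assert in_quadrant / top.sum() >= 0.6
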