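import numpy as np
import pytest

from lodgeseg.network import NetworkSpec, build_mobile_unet
from lodgeseg.raster_io import Raster
from lodgeseg.synthetic import SceneConfig, generate_dataset
from lodgeseg.training import (
    TrainConfig,
    evaluate_model,
    predict,
    split_dataset,
    train,
)


class TestSplit:
    def test_1500_splits_to_1200_150_150(self):
        parts = split_dataset(list(range(1500)), (0.8, 0.1, 0.1), seed=1)
        assert tuple(len(p) for p in parts) == (1200, 150, 150)

    def test_exact_small_division(self):
        parts = split_dataset(list(range(10)), (0.8, 0.1, 0.1), seed=0)
        assert tuple(len(p) for p in parts) == (8, 1, 1)

    def test_partition_property(self):
        items = list(range(103))
        tr, va, te = split_dataset(items, (0.8, 0.1, 0.1), seed=2)
        assert sorted(tr + va + te) == items
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))
        assert len(tr) == 103 - 10 - 10  # remainder goes to train

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError, match="ratios"):
            split_dataset([1, 2], (0.5, 0.4, 0.2), seed=0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            split_dataset([], seed=0)

    def test_seeded_shuffle_reproducible(self):
        a = split_dataset(list(range(50)), seed=9)
        b = split_dataset(list(range(50)), seed=9)
        assert a == b


class TestConfig:
    def test_recipe_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == pytest.approx(1e-4)
        assert cfg.batch_size == 4
        assert cfg.epochs == 200

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            TrainConfig(learning_rate=0.0)


def _tiny_setup(seed=0, epochs=3, in_channels=4):
    ds = generate_dataset(SceneConfig(height=64, width=64, seed=seed), 3, tile=32)
    pairs = ds.rgb_dsm if in_channels == 4 else ds.rgb
    spec = NetworkSpec.variant("table1", in_channels=in_channels, width_divisor=16, tile=32)
    model = build_mobile_unet(spec, seed=seed)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=2, epochs=epochs, seed=seed)
    return model, pairs, cfg


class TestTraining:
    def test_losses_finite_and_history_complete(self):
        model, pairs, cfg = _tiny_setup(epochs=3)
        model, hist = train(model, pairs[:2], pairs[2:3], cfg)
        assert len(hist.records) == 3
        for r in hist.records:
            assert np.isfinite(r.train_loss) and r.train_loss >= 0
            assert 0 <= r.val_accuracy <= 1
        assert 1 <= hist.best_epoch <= 3

    def test_best_checkpoint_weights_are_restored(self):
        """Returned weights reproduce the best recorded validation accuracy,
        not necessarily the final epoch's."""
        from lodgeseg.training import _epoch_eval, to_arrays

        model, pairs, cfg = _tiny_setup(epochs=4)
        model, hist = train(model, pairs[:2], pairs[2:3], cfg)
        x, y = to_arrays(pairs[2:3])
        _, acc = _epoch_eval(model, x, y, 2)
        assert acc == pytest.approx(hist.best_val_accuracy, abs=1e-9)

    def test_same_seed_gives_identical_history(self):
        m1, pairs, cfg = _tiny_setup(epochs=2)
        m2, _, _ = _tiny_setup(epochs=2)
        _, h1 = train(m1, pairs[:2], pairs[2:3], cfg)
        _, h2 = train(m2, pairs[:2], pairs[2:3], cfg)
        for a, b in zip(h1.records, h2.records):
            assert a.train_loss == b.train_loss
            assert a.val_accuracy == b.val_accuracy

    def test_channel_mismatch_is_contract_error(self):
        model, _, cfg = _tiny_setup(in_channels=4)
        ds = generate_dataset(SceneConfig(height=32, width=32, seed=1), 1, tile=32)
        with pytest.raises(ValueError, match="channels"):
            train(model, ds.rgb, ds.rgb, cfg)

    def test_empty_sets_rejected(self):
        model, pairs, cfg = _tiny_setup()
        with pytest.raises(ValueError, match="nonempty"):
            train(model, [], pairs[:1], cfg)

    def test_history_csv(self, tmp_path):
        model, pairs, cfg = _tiny_setup(epochs=2)
        _, hist = train(model, pairs[:2], pairs[2:3], cfg)
        hist.to_csv(tmp_path / "h.csv")
        lines = (tmp_path / "h.csv").read_text().strip().splitlines()
        assert len(lines) == 3 and lines[0].startswith("epoch,")


class TestPredict:
    def test_argmax_and_tie_break(self):
        """Per-pixel argmax with ties toward the lowest class index."""
        probs = np.array([0.1, 0.7, 0.2])
        assert int(probs.argmax()) == 1
        tie = np.array([1 / 3, 1 / 3, 1 / 3])
        assert int(tie.argmax()) == 0

    def test_output_shape_and_labels(self, trained_small_model):
        model, cfg = trained_small_model
        ds = generate_dataset(SceneConfig(height=64, width=64, seed=99), 1, tile=64)
        mask = predict(model, ds.rgb_dsm[0].image)
        assert mask.shape == (64, 64)
        assert set(np.unique(mask.labels)) <= {0, 1, 2}

    def test_trained_model_beats_chance_comfortably(self, trained_small_model):
        model, cfg = trained_small_model
        ds = generate_dataset(SceneConfig(height=128, width=128, seed=123), 2, tile=64)
        report, cm = evaluate_model(model, ds.rgb_dsm)
        assert report.accuracy > 0.8
        assert report.miou > 0.5

    def test_channel_mismatch_rejected(self, trained_small_model):
        model, _ = trained_small_model
        bad = Raster(np.zeros((64, 64, 3)), ("R", "G", "B"))
        with pytest.raises(ValueError, match="channels"):
            predict(model, bad)
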