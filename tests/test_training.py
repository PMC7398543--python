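"""Dataset assembly, optimizer behavior, and patch-stitched prediction."""

import copy

import numpy as np
import pytest

import patchunet as pu
from patchunet.errors import ValidationError
from patchunet.network import UNet
from patchunet.patching import decode_onehot

PIPE32 = pu.PipelineConfig(
    plane="axial", canvas_size=32, patch_size=16, slice_count=2, slice_interval=2
)


@pytest.fixture(scope="module")
def tiny_volumes():
    cfg = pu.PhantomConfig(canvas=32, n_slices=6, seed=21)
    train, test, _ = pu.make_phantom_suite(3, 1, cfg, seed=21)
    return train, test


class TestMakeTrainingSet:
    def test_pair_count_is_product_of_config(self, tiny_volumes):
        train, _ = tiny_volumes
        pairs = pu.make_training_set(train, PIPE32)
        # 3 volumes x 2 slices x (32/16)^2 patches
        assert len(pairs) == 3 * 2 * 4

    def test_targets_are_one_hot(self, tiny_volumes):
        train, _ = tiny_volumes
        pairs = pu.make_training_set(train, PIPE32)
        for img, target in pairs[:4]:
            assert img.shape == (16, 16)
            assert target.shape == (16, 16, 4)
            assert np.all(target.sum(axis=-1) == 1)

    def test_whole_canvas_patch_is_identity(self, tiny_volumes):
        train, _ = tiny_volumes
        cfg = pu.PipelineConfig(
            plane="axial", canvas_size=32, patch_size=32, slice_count=1, slice_interval=1
        )
        pairs = pu.make_training_set(train[:1], cfg)
        assert len(pairs) == 1
        vol = pu.normalize_intensity(train[0])
        mid = pu.select_training_slices(6, 1, 1)[0]
        expected = pu.extract_slices(vol, "axial")[mid].pixels
        assert np.array_equal(pairs[0][0], expected)

    def test_unlabelled_volume_rejected(self):
        vol = pu.Volume(intensities=np.zeros((4, 32, 32)))
        with pytest.raises(ValidationError, match="labels"):
            pu.make_training_set([vol], PIPE32)


@pytest.fixture(scope="module")
def pairs(tiny_volumes):
    return pu.make_training_set(tiny_volumes[0], PIPE32)


@pytest.fixture(scope="module")
def padded_slice(tiny_volumes):
    _, test = tiny_volumes
    vol = pu.normalize_intensity(test[0])
    s = pu.extract_slices(vol, "axial")[3]
    return pu.pad_to_canvas(s, 32)


class TestTrain:
    def _net(self, seed=0):
        return UNet(pu.ModelSpec(patch_size=16, base_filters=4, depth=2), seed=seed)

    def test_zero_learning_rate_leaves_weights_bitwise_unchanged(self, pairs):
        net = self._net()
        before = copy.deepcopy(net.params)
        pu.train(net, pairs, pu.TrainConfig(learning_rate=0.0, epochs=1, batch_size=4))
        for name in before:
            assert np.array_equal(net.params[name]["W"], before[name]["W"])
            assert np.array_equal(net.params[name]["b"], before[name]["b"])

    def test_same_seed_reproduces_report_and_weights(self, pairs):
        cfg = pu.TrainConfig(epochs=3, batch_size=4, seed=11)
        net_a, rep_a = pu.train(self._net(5), pairs, cfg)
        net_b, rep_b = pu.train(self._net(5), pairs, cfg)
        assert rep_a.losses == rep_b.losses
        assert rep_a.accuracies == rep_b.accuracies
        for name in net_a.params:
            assert np.array_equal(net_a.params[name]["W"], net_b.params[name]["W"])

    def test_loss_decreases_over_training(self, pairs):
        _, report = pu.train(
            self._net(1), pairs, pu.TrainConfig(epochs=15, batch_size=4, seed=1)
        )
        assert report.losses[-1] < report.losses[0]
        assert all(np.isfinite(l) and l >= 0 for l in report.losses)
        assert report.epochs == 15 == len(report.losses)

    def test_early_stopping_halts_before_epoch_budget(self, pairs):
        cfg = pu.TrainConfig(
            epochs=40, batch_size=4, seed=2, early_stopping=True,
            val_fraction=0.25, patience=2, learning_rate=0.0,
        )
        # lr=0 never improves validation loss, so patience triggers at once
        _, report = pu.train(self._net(), pairs, cfg)
        assert report.epochs == 1 + cfg.patience
        assert len(report.val_losses) == report.epochs

    def test_augmentation_hook_is_applied(self, pairs):
        calls = []

        def null_augment(rng, xb, yb):
            calls.append(len(xb))
            return xb, yb

        cfg = pu.TrainConfig(epochs=1, batch_size=4, seed=0)
        net_a, rep_a = pu.train(self._net(3), pairs, cfg, augment=null_augment)
        net_b, rep_b = pu.train(self._net(3), pairs, cfg)
        assert sum(calls) == len(pairs)
        # identity augmentation must not change the optimization
        assert rep_a.losses == rep_b.losses

    def test_channel_mismatch_rejected(self, pairs):
        net = UNet(pu.ModelSpec(patch_size=16, base_filters=2, depth=2, n_classes=3))
        with pytest.raises(ValidationError, match="channels"):
            pu.train(net, pairs, pu.TrainConfig(epochs=1))

    def test_empty_data_rejected(self):
        with pytest.raises(ValidationError, match="no training data"):
            pu.train(self._net(), [], pu.TrainConfig())


class TestPrediction:
    def test_prediction_matches_manual_patch_assembly(self, padded_slice):
        net = UNet(pu.ModelSpec(patch_size=16, base_filters=4, depth=2), seed=2)
        pred = pu.predict_slice(net, padded_slice, PIPE32)
        # loop oracle: forward each patch separately, paste scores, argmax
        canvas_scores = np.zeros((32, 32, 4))
        grid = pu.split_nonoverlapping(padded_slice, 16)
        for patch, (r, c) in zip(grid.patches, grid.offsets):
            canvas_scores[r : r + 16, c : c + 16] = net.forward(patch[None])[0]
        assert np.array_equal(pred, decode_onehot(canvas_scores))

    def test_overlap_with_stride_p_equals_nonoverlap(self, padded_slice):
        net = UNet(pu.ModelSpec(patch_size=16, base_filters=4, depth=2), seed=3)
        non = pu.predict_slice(net, padded_slice, PIPE32)
        import dataclasses

        over_cfg = dataclasses.replace(PIPE32, mode="overlap", stride=16)
        over = pu.predict_slice(net, padded_slice, over_cfg)
        assert np.array_equal(non, over)

    def test_non_canvas_slice_rejected(self):
        net = UNet(pu.ModelSpec(patch_size=16, base_filters=2, depth=2))
        with pytest.raises(ValidationError, match="canvas"):
            pu.predict_slice(net, pu.SliceImage(pixels=np.zeros((16, 20))), PIPE32)

    def test_predict_volume_equals_slice_loop(self, tiny_volumes):
        _, test = tiny_volumes
        net = UNet(pu.ModelSpec(patch_size=16, base_filters=4, depth=2), seed=4)
        pred = pu.predict_volume(net, test[0], PIPE32)
        assert pred.labels.shape == test[0].shape
        assert set(np.unique(pred.labels)) <= {0, 1, 2, 3}
        vol_n = pu.normalize_intensity(test[0], "minmax")
        for i, s in enumerate(pu.extract_slices(vol_n, "axial")):
            manual = pu.predict_slice(net, pu.pad_to_canvas(s, 32), PIPE32)
            assert np.array_equal(
                np.moveaxis(pred.labels, 0, 0)[i], manual
            )  # canvas == native size here: no unpad crop

    def test_predict_volume_preserves_native_geometry(self, tiny_volumes):
        # non-square native slices exercise the unpad path
        rng = np.random.default_rng(0)
        vol = pu.Volume(
            intensities=rng.normal(size=(4, 24, 30)),
            labels=rng.integers(0, 4, size=(4, 24, 30)),
            axis_names=("axial", "coronal", "sagittal"),
        )
        net = UNet(pu.ModelSpec(patch_size=16, base_filters=2, depth=2), seed=0)
        pred = pu.predict_volume(net, vol, PIPE32)
        assert pred.labels.shape == (4, 24, 30)
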