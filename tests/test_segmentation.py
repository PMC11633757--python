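"""Chessboard partitioning, augmentation, model construction, training
semantics and majority-vote tiled inference."""

import numpy as np
import pytest

from endoseg.architecture import ModelSpec, parameter_counts, unet3plus_layers
from endoseg.images import AnnotationMask, MultimodalImage
from endoseg.segmentation import (
    AugmentConfig,
    TrainConfig,
    augment,
    build_model,
    center_crop,
    chessboard_split,
    predict_tiled,
    train,
)
from endoseg.synthetic import PhantomSpec, generate_label_map, render_multimodal


def _mosaic_and_labels(side=128, seed=0):
    spec = PhantomSpec(shape=(side, side), seed=seed, blob_scale_px=12)
    mask = generate_label_map(spec)
    return render_multimodal(mask, seed=seed), mask


class TestChessboardSplit:
    def test_4x4_grid_counts(self):
        mosaic, labels = _mosaic_and_labels(128)
        train_set, test_set = chessboard_split(mosaic, labels, patch_px=32)
        assert len(test_set) == 8 and len(train_set) == 8

    def test_3x3_grid_counts(self):
        """Corners share the white/test parity: 5 test vs 4 train."""
        mosaic, labels = _mosaic_and_labels(96)
        train_set, test_set = chessboard_split(mosaic, labels, patch_px=32)
        assert len(test_set) == 5 and len(train_set) == 4

    def test_partition_disjoint_and_exhaustive(self):
        mosaic, labels = _mosaic_and_labels(160)
        train_set, test_set = chessboard_split(mosaic, labels, patch_px=32)
        positions = [p.position for p in train_set.patches + test_set.patches]
        assert len(positions) == len(set(positions)) == 25
        for p in train_set.patches:
            assert (p.position[0] + p.position[1]) % 2 == 1
        for p in test_set.patches:
            assert (p.position[0] + p.position[1]) % 2 == 0

    def test_border_patches_dropped(self):
        mosaic, labels = _mosaic_and_labels(150)  # 150 = 4*32 + 22 remainder
        train_set, test_set = chessboard_split(mosaic, labels, patch_px=32)
        assert len(train_set) + len(test_set) == 16

    def test_too_small_mosaic_raises(self):
        mosaic, labels = _mosaic_and_labels(64)
        with pytest.raises(ValueError, match="smaller"):
            chessboard_split(mosaic, labels, patch_px=128)


class TestAugment:
    @pytest.fixture()
    def patch(self):
        mosaic, labels = _mosaic_and_labels(64, seed=3)
        return mosaic.data, labels.labels

    def test_disabled_augmentation_is_center_crop(self, patch):
        img, lab = patch
        cfg = AugmentConfig.disabled(crop_px=56, out_px=48)
        out_img, out_lab = augment(img, lab, seed=0, config=cfg)
        exp_img, exp_lab = center_crop(*center_crop(img, lab, 56), 48)
        assert np.array_equal(out_img, exp_img)
        assert np.array_equal(out_lab, exp_lab)

    def test_flip_is_involution(self, patch):
        img, lab = patch
        cfg = AugmentConfig(
            p_perspective=0, p_rotation=0, p_flip=1.0, p_contrast=0, p_brightness=0,
            crop_px=64, out_px=64,
        )
        out_img, out_lab = augment(img, lab, seed=11, config=cfg)
        # the result is a single flip of the full patch along some axis
        assert any(
            np.array_equal(out_lab, np.flip(lab, axis=a)) for a in (0, 1)
        )
        for a in (0, 1):
            if np.array_equal(out_lab, np.flip(lab, axis=a)):
                assert np.array_equal(np.flip(out_img, axis=a + 1), img)

    def test_geometric_transforms_add_no_labels(self, patch):
        img, lab = patch
        cfg = AugmentConfig(
            p_perspective=1.0, p_rotation=1.0, p_flip=1.0, p_contrast=0, p_brightness=0,
            crop_px=56, out_px=48,
        )
        for seed in range(5):
            _, out_lab = augment(img, lab, seed=seed, config=cfg)
            assert set(np.unique(out_lab)) <= set(np.unique(lab))

    def test_deterministic_given_seed(self, patch):
        img, lab = patch
        cfg = AugmentConfig(crop_px=56, out_px=48)
        a = augment(img, lab, seed=21, config=cfg)
        b = augment(img, lab, seed=21, config=cfg)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_small_patch_rejected(self, patch):
        img, lab = patch
        with pytest.raises(ValueError, match="smaller"):
            augment(img, lab, seed=0, config=AugmentConfig(crop_px=226, out_px=224))


class TestBuildModel:
    def test_six_class_parameter_budget(self):
        counts = parameter_counts(ModelSpec(n_classes=6, n_stacks=5))
        assert counts.total_millions == pytest.approx(35.9, rel=0.02)
        assert counts.frozen == 14_714_688

    def test_three_class_parameter_budget(self):
        counts = parameter_counts(ModelSpec(n_classes=3, n_stacks=4))
        assert counts.total_millions == pytest.approx(32.2, rel=0.02)
        assert counts.trainable / 1e6 == pytest.approx(17.5, abs=0.1)

    def test_frozen_count_shared_across_variants(self):
        c6 = parameter_counts(ModelSpec(n_classes=6, n_stacks=5))
        c3 = parameter_counts(ModelSpec(n_classes=3, n_stacks=4))
        assert c6.frozen == c3.frozen

    def test_layer_graph_structure(self):
        layers = unet3plus_layers(ModelSpec(n_classes=6, n_stacks=5))
        names = [l.name for l in layers]
        assert names.count("head") == 1
        assert sum(n.startswith("block") for n in names) == 13  # VGG16 convs
        assert sum("fusion" in n for n in names) == 5  # five up-sampling stacks
        assert all(not l.trainable for l in layers if l.name.startswith("block"))

    def test_desk_scale_model_flagged_and_excluded_from_counts(self):
        spec = ModelSpec(n_classes=6, n_stacks=2, input_px=16, width_factor=1 / 16)
        assert spec.desk_scale
        model = build_model(spec, seed=0)
        assert model.network is not None
        assert model.counts.total < 1e6
        with pytest.raises(ValueError, match="full-scale"):
            unet3plus_layers(spec)

    def test_unsupported_stacks_raise(self):
        with pytest.raises(ValueError, match="n_stacks"):
            ModelSpec(n_classes=6, n_stacks=3)  # full scale allows only 4 or 5


def _tiny_spec(n_classes=6):
    return ModelSpec(n_classes=n_classes, n_stacks=2, input_px=16, width_factor=1 / 16)


def _tiny_patchset(side=96, seed=0, constant_label=None):
    mosaic, mask = _mosaic_and_labels(side, seed=seed)
    if constant_label is not None:
        mask = AnnotationMask(np.full_like(mask.labels, constant_label), level=6)
    return chessboard_split(mosaic, mask, patch_px=32)


class TestTrain:
    def test_loss_decreases_on_synthetic_set(self):
        train_set, _ = _tiny_patchset()
        model = build_model(_tiny_spec(), seed=0)
        cfg = TrainConfig(
            epochs=8, patience=8, batch_size=4, learning_rate=3e-3,
            n_val_tiles=1, seed=0, steps_per_epoch=3,
        )
        model = train(model, train_set, cfg)
        hist = model.history["train_loss"]
        assert hist[-1] < hist[0]
        assert len(model.history["val_loss"]) == len(hist)

    def test_constant_label_task_learned(self):
        """A constant-label dataset is predicted almost perfectly."""
        train_set, test_set = _tiny_patchset(constant_label=4)
        model = build_model(_tiny_spec(), seed=1)
        cfg = TrainConfig(
            epochs=6, patience=6, batch_size=4, learning_rate=5e-3,
            n_val_tiles=1, seed=1, steps_per_epoch=3,
        )
        model = train(model, train_set, cfg)
        correct = total = 0
        for patch in test_set.patches:
            img, lab = center_crop(patch.image, patch.labels, 16)
            pred = model.network.predict_proba(img[None])[0].argmax(axis=0)
            correct += (pred == lab).sum()
            total += lab.size
        assert correct / total >= 0.99

    def test_early_stopping_semantics(self):
        """Patience 1 with a frozen learning rate stops after exactly 2 epochs."""
        train_set, _ = _tiny_patchset()
        model = build_model(_tiny_spec(), seed=2)
        cfg = TrainConfig(
            epochs=50, patience=1, batch_size=4, learning_rate=0.0,
            n_val_tiles=1, seed=2, steps_per_epoch=1,
        )
        model = train(model, train_set, cfg)
        assert len(model.history["train_loss"]) == 2

    def test_validation_split_too_large_raises(self):
        train_set, _ = _tiny_patchset()
        model = build_model(_tiny_spec(), seed=0)
        cfg = TrainConfig(epochs=1, patience=1, batch_size=4, n_val_tiles=len(train_set), seed=0)
        with pytest.raises(ValueError, match="validation"):
            train(model, train_set, cfg)

    def test_untrained_model_cannot_predict(self):
        mosaic, _ = _mosaic_and_labels(64)
        model = build_model(_tiny_spec(), seed=0)
        with pytest.raises(ValueError, match="trained"):
            predict_tiled(model, mosaic, n_shifts=1)


@pytest.fixture(scope="module")
def trained_model():
    spec = PhantomSpec(shape=(96, 96), seed=5, blob_scale_px=12)
    mask = generate_label_map(spec)
    mosaic = render_multimodal(mask, seed=5)
    train_set, _ = chessboard_split(mosaic, mask, patch_px=32)
    model = build_model(_tiny_spec(), seed=5)
    cfg = TrainConfig(
        epochs=10, patience=10, batch_size=4, learning_rate=3e-3,
        n_val_tiles=1, seed=5, steps_per_epoch=3,
    )
    return train(model, train_set, cfg), mosaic


class TestPredictTiled:
    def test_single_zero_shift_equals_plain_tiling(self, trained_model):
        model, mosaic = trained_model
        voted = predict_tiled(model, mosaic, n_shifts=1, seed=0)
        plain = predict_tiled(model, mosaic, offsets=[(0, 0)])
        assert np.array_equal(voted.labels, plain.labels)

    def test_unanimous_votes_return_that_prediction(self, trained_model):
        model, mosaic = trained_model
        repeated = predict_tiled(model, mosaic, offsets=[(0, 0)] * 7)
        single = predict_tiled(model, mosaic, offsets=[(0, 0)])
        assert np.array_equal(repeated.labels, single.labels)

    def test_vote_invariant_under_shift_permutation(self, trained_model):
        model, mosaic = trained_model
        offsets = [(0, 0), (3, 5), (7, 1), (12, 9), (2, 14)]
        a = predict_tiled(model, mosaic, offsets=offsets)
        b = predict_tiled(model, mosaic, offsets=offsets[::-1])
        assert np.array_equal(a.labels, b.labels)

    def test_output_shape_and_label_range(self, trained_model):
        model, mosaic = trained_model
        pred = predict_tiled(model, mosaic, n_shifts=3, seed=1)
        assert pred.labels.shape == mosaic.shape
        assert pred.labels.min() >= 0
        assert pred.labels.max() < model.n_classes

    def test_deterministic_given_seed(self, trained_model):
        model, mosaic = trained_model
        a = predict_tiled(model, mosaic, n_shifts=4, seed=3)
        b = predict_tiled(model, mosaic, n_shifts=4, seed=3)
        assert np.array_equal(a.labels, b.labels)
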