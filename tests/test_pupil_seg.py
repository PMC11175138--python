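"""Eye splitting, preprocessing, augmentation, U-Net and mask metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nystrack import nn
from nystrack.pupil_seg import (SegConfig, augment, build_unet,
                                eval_segmentation, hflip_pair, preprocess,
                                rotate_pair, segment, shift_pair, split_eyes,
                                train_segmenter, unet_param_count,
                                save_segmenter, load_segmenter)


def _unet_params_oracle(depth, base):
    """Independent per-layer parameter count: each 3x3 conv c_in->c_out has
    9*c_in*c_out weights + c_out biases; the pattern is two convs per
    encoder level, two in the bottleneck, and per decoder level one
    up-convolution plus two convs on the concatenated (doubled) channels,
    closing with a 1x1 conv to one channel."""
    total = 0
    c_prev = 1
    widths = [base * 2 ** i for i in range(depth + 1)]
    for w in widths[:-1]:
        total += 9 * c_prev * w + w + 9 * w * w + w
        c_prev = w
    wb = widths[-1]
    total += 9 * widths[-2] * wb + wb + 9 * wb * wb + wb
    for i in range(depth - 1, -1, -1):
        w = widths[i]
        total += 9 * widths[i + 1] * w + w      # up-conv
        total += 9 * (2 * w) * w + w + 9 * w * w + w
    total += 1 * widths[0] * 1 + 1
    return total


class TestSplitEyes:
    def test_constant_frame_two_constant_halves(self):
        left, right = split_eyes(np.full((120, 320), 7, np.uint8))
        assert left.shape == right.shape == (120, 160)
        assert np.all(left == 7) and np.all(right == 7)

    def test_bright_pixel_lands_in_right_half(self):
        frame = np.zeros((120, 320), np.uint8)
        frame[50, 200] = 255
        left, right = split_eyes(frame)
        assert left.max() == 0
        assert right[50, 40] == 255

    def test_partition_is_lossless(self):
        rng = np.random.default_rng(0)
        frame = rng.integers(0, 256, (120, 320)).astype(np.uint8)
        left, right = split_eyes(frame)
        np.testing.assert_array_equal(np.hstack([left, right]), frame)

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            split_eyes(np.zeros((10, 11)))


class TestPreprocess:
    def test_target_size_and_range(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, (120, 160)).astype(np.uint8)
        out = preprocess(img)
        assert out.shape == (240, 320)  # 320 wide x 240 high
        assert out.min() >= 0 and out.max() <= 1

    def test_constant_image_scales_to_fraction(self):
        out = preprocess(np.full((120, 160), 128, np.uint8))
        np.testing.assert_allclose(out, 128 / 255, atol=1e-6)

    def test_masks_stay_binary_under_nearest_neighbour(self):
        mask = np.zeros((60, 80), np.uint8)
        mask[20:40, 30:50] = 255
        out = preprocess(mask, size=(320, 240), is_mask=True)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_three_channel_input_collapsed(self):
        img = np.zeros((60, 80, 3), np.uint8)
        img[..., 0] = 90
        out = preprocess(img, size=(80, 60))
        assert out.shape == (60, 80)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((0, 0)))


class TestAugment:
    def test_double_flip_is_identity(self):
        rng = np.random.default_rng(2)
        img = rng.random((40, 60)).astype(np.float32)
        mask = (rng.random((40, 60)) > 0.8).astype(np.float32)
        f_img, f_mask = hflip_pair(*hflip_pair(img, mask))
        np.testing.assert_array_equal(f_img, img)
        np.testing.assert_array_equal(f_mask, mask)

    def test_zero_rotation_is_identity_on_mask(self):
        mask = np.zeros((40, 60), np.float32)
        mask[10:20, 20:35] = 1
        img = mask.copy()
        _, m = rotate_pair(img, mask, 0.0)
        np.testing.assert_array_equal(m, mask)

    def test_shift_moves_mask_centroid_by_exact_pixels(self):
        mask = np.zeros((240, 320), np.float32)
        mask[100:140, 100:140] = 1
        img = mask.copy()
        _, m = shift_pair(img, mask, 0.05)  # +5% of 320 = 16 px
        c0 = np.nonzero(mask)[1].mean()
        c1 = np.nonzero(m)[1].mean()
        assert c1 - c0 == pytest.approx(16.0, abs=1e-9)

    def test_three_variants_with_aligned_transforms(self):
        # using the mask itself as the image exposes any transform mismatch
        mask = np.zeros((48, 64), np.float32)
        mask[10:30, 20:40] = 1
        variants = augment(mask.copy(), mask, seed=11)
        assert len(variants) == 3
        for img, msk in variants:
            assert img.shape == msk.shape == mask.shape
            overlap = np.sum((img > 0.5) & (msk > 0.5))
            union = np.sum((img > 0.5) | (msk > 0.5))
            assert overlap / union > 0.99

    def test_augment_is_seeded(self):
        rng = np.random.default_rng(3)
        img = rng.random((32, 32)).astype(np.float32)
        mask = (img > 0.5).astype(np.float32)
        a = augment(img, mask, seed=5)
        b = augment(img, mask, seed=5)
        for (ia, ma), (ib, mb) in zip(a, b):
            np.testing.assert_array_equal(ia, ib)
            np.testing.assert_array_equal(ma, mb)


class TestUNet:
    def test_output_matches_input_spatial_shape(self):
        cfg = SegConfig(depth=2, base_filters=4, input_size=(32, 16))
        model = build_unet(cfg, seed=0)
        x = np.zeros((2, 16, 32, 1), np.float32)
        probs = model.predict(x)
        assert probs.shape == (2, 16, 32, 1)
        assert np.all((probs >= 0) & (probs <= 1))

    @pytest.mark.parametrize("depth,base", [(2, 4), (3, 8), (4, 16)])
    def test_parameter_count_matches_independent_formula(self, depth, base):
        size = (2 ** depth * 4, 2 ** depth * 2)
        model = build_unet(SegConfig(depth=depth, base_filters=base,
                                     input_size=size))
        assert model.n_params() == _unet_params_oracle(depth, base)
        assert model.n_params() == unet_param_count(depth, base)

    def test_parameter_count_grows_with_base_filters(self):
        small = unet_param_count(3, 8)
        large = unet_param_count(3, 16)
        assert large > small

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            SegConfig(depth=4, base_filters=8, input_size=(100, 60)).validate()


def _disc_sample(size=(32, 32), center=(16, 14), radius=6):
    h, w = size[1], size[0]
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2
            <= radius ** 2).astype(np.float32)
    img = 0.8 - 0.6 * mask + 0.05 * np.cos(xx / 5)
    return img.astype(np.float32), mask


class TestTraining:
    def test_overfits_single_sample(self):
        img, mask = _disc_sample()
        cfg = SegConfig(depth=2, base_filters=8, input_size=(32, 32),
                        learning_rate=1e-3, epochs=50, batch_size=1)
        model, history = train_segmenter((img[None], mask[None]),
                                         (img[None], mask[None]), cfg, seed=0)
        pred = segment(model, img)
        rep = eval_segmentation(pred[None], mask[None])
        assert rep["mean"]["dsc"] >= 95.0
        assert history["train_loss"][history["best_epoch"]] \
            < history["train_loss"][0]

    def test_same_seed_identical_history(self):
        img, mask = _disc_sample()
        imgs = np.stack([img, img[::-1].copy()])
        masks = np.stack([mask, mask[::-1].copy()])
        cfg = SegConfig(depth=2, base_filters=4, input_size=(32, 32),
                        epochs=3, batch_size=2, learning_rate=1e-3)
        _, h1 = train_segmenter((imgs, masks), (imgs, masks), cfg, seed=7)
        _, h2 = train_segmenter((imgs, masks), (imgs, masks), cfg, seed=7)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_checkpoint_round_trip(self, tmp_path):
        img, mask = _disc_sample()
        cfg = SegConfig(depth=2, base_filters=4, input_size=(32, 32),
                        epochs=2, batch_size=1, learning_rate=1e-3)
        model, _ = train_segmenter((img[None], mask[None]),
                                   (img[None], mask[None]), cfg, seed=0)
        path = tmp_path / "seg.npz"
        save_segmenter(path, model)
        loaded = load_segmenter(path)
        np.testing.assert_array_equal(segment(model, img),
                                      segment(loaded, img))


class TestSegmentThreshold:
    def test_extreme_thresholds_and_monotonicity(self):
        cfg = SegConfig(depth=2, base_filters=4, input_size=(16, 16))
        model = build_unet(cfg, seed=1)
        img = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        assert segment(model, img, mask_threshold=1.0).sum() == 0
        assert segment(model, img, mask_threshold=0.0).sum() == 16 * 16
        low = segment(model, img, mask_threshold=0.3)
        high = segment(model, img, mask_threshold=0.7)
        assert np.all(low >= high)  # lowering threshold never shrinks


class TestEvalSegmentation:
    def test_identical_masks_score_perfect(self):
        mask = (np.random.default_rng(1).random((2, 20, 20)) > 0.7)
        rep = eval_segmentation(mask, mask)
        for key in ("sensitivity", "precision", "accuracy", "dsc"):
            assert rep["mean"][key] == pytest.approx(100.0)

    def test_complement_scores_zero(self):
        mask = np.zeros((1, 10, 10), bool)
        mask[0, :5] = True
        rep = eval_segmentation(~mask, mask)
        assert rep["mean"]["sensitivity"] == 0.0
        assert rep["mean"]["specificity"] == 0.0

    def test_equal_area_false_region_gives_dsc_two_thirds(self):
        gt = np.zeros((1, 10, 20), bool)
        gt[0, :, :10] = True          # 100 px ground truth
        pred = np.ones((1, 10, 20), bool)  # covers gt + 100 false px
        rep = eval_segmentation(pred, gt)
        assert rep["mean"]["dsc"] == pytest.approx(200 / 300 * 100)

    def test_undefined_metrics_excluded_from_mean(self):
        gt = np.zeros((2, 5, 5), bool)
        gt[0, 0, 0] = True
        pred = gt.copy()
        rep = eval_segmentation(pred, gt)
        # image 2 has no foreground: sensitivity undefined there
        assert np.isnan(rep["per_image"]["sensitivity"][1])
        assert rep["mean"]["sensitivity"] == pytest.approx(100.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metrics_match_brute_force_pixel_counts(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.random((1, 8, 8)) > 0.5
        gt = rng.random((1, 8, 8)) > 0.5
        rep = eval_segmentation(pred, gt)
        tp = fp = fn = tn = 0
        for i in range(8):
            for j in range(8):
                if pred[0, i, j] and gt[0, i, j]:
                    tp += 1
                elif pred[0, i, j]:
                    fp += 1
                elif gt[0, i, j]:
                    fn += 1
                else:
                    tn += 1
        acc = 100 * (tp + tn) / 64
        assert rep["mean"]["accuracy"] == pytest.approx(acc)
        if 2 * tp + fp + fn:
            dsc = 100 * 2 * tp / (2 * tp + fp + fn)
            assert rep["mean"]["dsc"] == pytest.approx(dsc)
        # DSC symmetry
        rep_ba = eval_segmentation(gt, pred)
        if np.isfinite(rep["mean"]["dsc"]):
            assert rep["mean"]["dsc"] == pytest.approx(rep_ba["mean"]["dsc"])
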