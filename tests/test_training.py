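"""Training recipe: split, augmentation, loss, Dice, snapshot selection."""

import math

import numpy as np
import pytest

from pupilkit.model import Prediction, SegmenterConfig, build_segmenter
from pupilkit.synth import EyeAppearance, LabeledFrame, render_frame
from pupilkit.training import (
    AugmentPolicy,
    TrainConfig,
    augment,
    dice,
    eval_crop,
    split_dataset,
    total_loss,
    train,
)

IDENTITY_POLICY = AugmentPolicy(
    rotation_range=0.0, crop_scale_range=(1.0, 1.0),
    horizontal_flip_p=0.0, vertical_flip_p=0.0,
    brightness_range=(1.0, 1.0), contrast_range=(1.0, 1.0), sharpness_range=(1.0, 1.0),
)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [(100, (70, 20, 10)), (10, (7, 2, 1)), (13, (9, 2, 2))])
    def test_sizes(self, n, expected):
        tr, va, te = split_dataset(list(range(n)), seed=0)
        assert (len(tr), len(va), len(te)) == expected

    def test_disjoint_cover(self):
        items = list(range(57))
        tr, va, te = split_dataset(items, seed=1)
        assert sorted(tr + va + te) == items

    def test_same_seed_same_membership(self):
        items = list(range(40))
        assert split_dataset(items, seed=5) == split_dataset(items, seed=5)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3], split=(0.5, 0.2, 0.2))


class TestAugment:
    def test_identity_policy_preserves_128px_frame(self, clean_frame):
        out = augment(clean_frame, IDENTITY_POLICY, seed=0)
        np.testing.assert_allclose(out.image, clean_frame.image, atol=1e-12)
        np.testing.assert_array_equal(out.mask, clean_frame.mask)
        assert out.blink == clean_frame.blink

    def test_horizontal_flip_is_involution(self, clean_frame):
        from dataclasses import replace

        policy = replace(IDENTITY_POLICY, horizontal_flip_p=1.0)
        once = augment(clean_frame, policy, seed=0)
        twice = augment(once, policy, seed=1)
        np.testing.assert_allclose(twice.image, clean_frame.image, atol=1e-12)
        np.testing.assert_array_equal(twice.mask, clean_frame.mask)

    def test_rotation_conserves_mask_area(self):
        # centered ellipse, 90 degree rotation: area changes < 2%
        from dataclasses import replace

        app = EyeAppearance(pupil_center=(63.5, 63.5), pupil_semi_axes=(18.0, 12.0),
                            noise_sigma=0.0)
        frame = render_frame(app, seed=0)
        policy = replace(IDENTITY_POLICY, rotation_range=90.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            out = augment(frame, policy, rng)
            assert out.mask.sum() == pytest.approx(frame.mask.sum(), rel=0.02)

    def test_geometric_transform_keeps_image_and_mask_in_register(self, clean_frame):
        # the pupil is the darkest structure; after any geometric transform the
        # mask must still cover dark pixels only
        policy = AugmentPolicy(brightness_range=(1.0, 1.0), contrast_range=(1.0, 1.0),
                               sharpness_range=(1.0, 1.0))
        rng = np.random.default_rng(7)
        for _ in range(10):
            out = augment(clean_frame, policy, rng)
            if out.mask.sum() > 20:
                inside = out.image[out.mask].mean()
                outside = out.image[~out.mask].mean()
                assert inside < outside

    def test_oversized_crop_rejected(self, clean_frame):
        from dataclasses import replace

        policy = replace(IDENTITY_POLICY, crop_scale_range=(1.5, 1.5))
        with pytest.raises(ValueError):
            augment(clean_frame, policy, seed=0)


class TestEvalCrop:
    def test_native_size_unchanged(self, clean_frame):
        assert eval_crop(clean_frame) is clean_frame

    def test_crop_centered_on_pupil_with_clamping(self):
        img = np.zeros((256, 256))
        mask = np.zeros((256, 256), dtype=bool)
        mask[60:69, 60:69] = True  # centroid (64, 64)
        frame = LabeledFrame(image=img, mask=mask, eye_present=True, blink=False)
        out = eval_crop(frame)
        assert out.image.shape == (128, 128)
        assert out.mask.sum() == 81  # window [0,128) x [0,128) keeps whole blob

    def test_blink_frame_center_crop(self):
        frame = LabeledFrame(image=np.zeros((256, 256)), mask=np.zeros((256, 256), dtype=bool),
                             eye_present=True, blink=True)
        out = eval_crop(frame)
        assert out.image.shape == (128, 128)


class TestTotalLoss:
    def test_perfect_prediction_near_zero(self, clean_frame):
        pred = Prediction(pupil_map=clean_frame.mask.astype(float), eye_prob=1.0, blink_prob=0.0)
        eps_term = -math.log(1 - 1e-7)
        assert total_loss(pred, clean_frame) <= 3 * eps_term + 1e-12

    def test_uniform_half_gives_3_ln2(self, clean_frame):
        pred = Prediction(pupil_map=np.full((128, 128), 0.5), eye_prob=0.5, blink_prob=0.5)
        assert total_loss(pred, clean_frame) == pytest.approx(3 * math.log(2), rel=1e-9)

    def test_matches_elementwise_oracle(self, clean_frame):
        rng = np.random.default_rng(0)
        pred = Prediction(pupil_map=rng.uniform(size=(128, 128)),
                          eye_prob=0.7, blink_prob=0.2)
        t = clean_frame.mask.astype(float)
        p = np.clip(pred.pupil_map, 1e-7, 1 - 1e-7)
        expected = 0.0
        # naive per-element loop, mean over pixels
        acc = 0.0
        for y in range(128):
            for x in range(128):
                acc += -(t[y, x] * math.log(p[y, x]) + (1 - t[y, x]) * math.log(1 - p[y, x]))
        expected += acc / (128 * 128)
        expected += -math.log(0.7)  # eye target 1
        expected += -math.log(1 - 0.2)  # blink target 0
        assert total_loss(pred, clean_frame) == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_rejected(self, clean_frame):
        pred = Prediction(pupil_map=np.zeros((64, 64)), eye_prob=0.5, blink_prob=0.5)
        with pytest.raises(ValueError):
            total_loss(pred, clean_frame)


class TestDice:
    def test_identity_disjoint_and_half(self):
        a = np.zeros((10, 10), dtype=bool)
        a[:5] = True
        assert dice(a, a) == 1.0
        assert dice(a, ~a) == 0.0
        b = np.zeros((20, 10), dtype=bool)
        c = np.zeros((20, 10), dtype=bool)
        b[:10] = True  # |A| = 100
        c[5:15] = True  # |B| = 100, overlap 50
        assert dice(b, c) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        e = np.zeros((5, 5), dtype=bool)
        assert dice(e, e) == 1.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform(size=(16, 16)) > 0.5
            b = rng.uniform(size=(16, 16)) > 0.5
            d = dice(a, b)
            assert d == dice(b, a)
            assert 0.0 <= d <= 1.0

    def test_set_arithmetic_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(size=(32, 32)) > 0.6
        b = rng.uniform(size=(32, 32)) > 0.6
        sa = {(i, j) for i, j in zip(*np.nonzero(a))}
        sb = {(i, j) for i, j in zip(*np.nonzero(b))}
        expected = 2 * len(sa & sb) / (len(sa) + len(sb))
        assert dice(a, b) == pytest.approx(expected)


TINY = SegmenterConfig(input_size=32, depth=2, convs_per_level=1, width=4,
                       expected_param_millions=None)


def tiny_frames(n, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n):
        app = EyeAppearance(
            image_size=32, pupil_center=(16 + rng.uniform(-4, 4), 16 + rng.uniform(-4, 4)),
            pupil_semi_axes=(5.0, 4.0), iris_radius=10.0, noise_sigma=0.02,
        )
        frames.append(render_frame(app, seed=int(rng.integers(2**31))))
    return frames


class TestTrainLoop:
    def test_one_epoch_history_and_snapshot(self):
        frames = tiny_frames(8)
        net = build_segmenter(TINY, seed=0)
        cfg = TrainConfig(epochs=1, batch_size=4, seed=0, augment=None)
        best, hist = train(net, frames[:6], frames[6:], cfg)
        assert len(hist) == 1
        assert set(hist[0]) == {"epoch", "train_loss", "val_dice"}

    def test_zero_learning_rate_freezes_validation_metric(self):
        frames = tiny_frames(8)
        net = build_segmenter(TINY, seed=0)
        cfg = TrainConfig(epochs=3, learning_rate=0.0, batch_size=4, seed=0, augment=None)
        _, hist = train(net, frames[:6], frames[6:], cfg)
        dices = [h["val_dice"] for h in hist]
        assert max(dices) - min(dices) < 1e-7

    def test_best_snapshot_is_argmax_of_history(self):
        frames = tiny_frames(12)
        net = build_segmenter(TINY, seed=1)
        cfg = TrainConfig(epochs=4, batch_size=4, seed=1, augment=None)
        best, hist = train(net, frames[:9], frames[9:], cfg)
        from pupilkit.training import evaluate_dice

        best_recorded = max(h["val_dice"] for h in hist)
        val = [f for f in frames[9:]]
        assert evaluate_dice(best, val) == pytest.approx(best_recorded, abs=1e-6)

    def test_empty_sets_rejected(self):
        net = build_segmenter(TINY)
        with pytest.raises(ValueError):
            train(net, [], tiny_frames(2), TrainConfig(epochs=1))


class TestBlinkHead:
    def test_blink_probability_separates_closed_eyes_after_training(self):
        """After training, closed-eye frames score higher blink probability
        than open-eye frames on a held-out synthetic set."""
        rng = np.random.default_rng(5)
        frames = []
        for i in range(160):
            blink = i % 10 < 3
            app = EyeAppearance(
                image_size=32,
                pupil_center=(16 + rng.uniform(-3, 3), 16 + rng.uniform(-3, 3)),
                pupil_semi_axes=(5.0, 4.0), iris_radius=10.0, noise_sigma=0.02,
                eyelid_openness=(rng.uniform(0.0, 0.12) if blink
                                 else rng.uniform(0.7, 1.0)),
            )
            frames.append(render_frame(app, seed=int(rng.integers(2**31))))
        rng.shuffle(frames)
        train_set, val_set = frames[:128], frames[128:]
        cfg = SegmenterConfig(input_size=32, expected_param_millions=None)
        net = build_segmenter(cfg, seed=0)
        best, _ = train(net, train_set, val_set,
                        TrainConfig(epochs=40, batch_size=8, seed=0, augment=None))
        _, _, blink_prob = best.predict_batch(np.stack([f.image for f in val_set]))
        is_blink = np.array([f.blink for f in val_set])
        assert is_blink.any() and (~is_blink).any()
        assert blink_prob[is_blink].mean() > blink_prob[~is_blink].mean() + 0.3
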