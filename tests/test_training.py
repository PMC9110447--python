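"""Balanced sampling, the one-cycle schedule, augmentation and short
end-to-end training runs on synthetic data."""

from collections import Counter

import numpy as np
import pytest

from surgphase import encoder as enc
from surgphase import training
from surgphase.losses import UNLABELLED
from surgphase.temporal import TCNConfig
from surgphase.training import TrainConfig, balanced_sample_indices, lr_at


class TestBalancedSampler:
    LABELS = {"v0": np.array([0] * 10 + [1] * 3), "v1": np.array([1] * 8 + [2])}

    def test_per_class_histogram_exactly_uniform(self):
        sample = balanced_sample_indices(self.LABELS, 5, seed=0, num_classes=3)
        flat = {"v0": self.LABELS["v0"], "v1": self.LABELS["v1"]}
        hist = Counter(int(flat[vid][i]) for vid, i in sample)
        assert hist == {0: 5, 1: 5, 2: 5}
        assert len(sample) == 15

    def test_paper_scale_epoch_size(self):
        labels = {"v": np.repeat(np.arange(7), 3000)}
        sample = balanced_sample_indices(labels, 2000, seed=1, num_classes=7)
        assert len(sample) == 14000

    def test_replacement_forced_for_small_classes(self):
        labels = {"a": np.array([0]), "b": np.array([1] * 10)}
        sample = balanced_sample_indices(labels, 3, seed=2, num_classes=2)
        assert sum(1 for vid, i in sample if vid == "a") == 3

    def test_without_replacement_when_pool_suffices(self):
        labels = {"v": np.array([0] * 10)}
        sample = balanced_sample_indices(labels, 10, seed=3, num_classes=1)
        assert sorted(i for _, i in sample) == list(range(10))

    def test_same_seed_identical_sample(self):
        a = balanced_sample_indices(self.LABELS, 4, seed=7, num_classes=3)
        b = balanced_sample_indices(self.LABELS, 4, seed=7, num_classes=3)
        assert list(a) == list(b)

    def test_absent_class_named_in_error(self):
        with pytest.raises(ValueError, match="class 2"):
            balanced_sample_indices({"v": np.array([0, 1])}, 2, seed=0,
                                    num_classes=3)


class TestSchedule:
    @pytest.mark.parametrize("batch,peak", [(32, 0.00625), (128, 0.025),
                                            (256, 0.05)])
    def test_peak_learning_rate_rule(self, batch, peak):
        cfg = TrainConfig(batch_size=batch)
        lrs = [lr_at(i, 200, cfg) for i in range(200)]
        assert np.isclose(max(lrs), peak, atol=1e-12)

    def test_peak_scales_linearly_in_batch(self):
        assert TrainConfig(batch_size=64).max_lr * 2 == TrainConfig(batch_size=128).max_lr

    def test_final_lr_below_one_percent_of_peak(self):
        cfg = TrainConfig(batch_size=128)
        assert lr_at(199, 200, cfg) < 0.01 * cfg.max_lr

    def test_warmup_then_decay_shape(self):
        cfg = TrainConfig(batch_size=128, warmup_fraction=0.3)
        lrs = [lr_at(i, 100, cfg) for i in range(100)]
        peak_idx = int(np.argmax(lrs))
        assert 25 <= peak_idx <= 35
        assert all(np.diff(lrs[:peak_idx]) >= 0)
        assert all(np.diff(lrs[peak_idx:]) <= 0)

    def test_step_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_at(200, 200, TrainConfig())


class TestAugmentation:
    def test_geometric_transform_shared_with_mask(self, rng):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        mask = np.full((32, 32), UNLABELLED)
        img[8:24, 8:24] = 200
        mask[8:24, 8:24] = 2
        out_img, out_mask = training.augment_frame(img, mask,
                                                   np.random.default_rng(5),
                                                   geometric=True, colour=False)
        bright = out_img[..., 0] > 100
        labelled = out_mask == 2
        # the mask moves with the image: overlap dominates either region
        overlap = np.sum(bright & labelled) / max(np.sum(bright | labelled), 1)
        assert overlap > 0.9
        assert set(np.unique(out_mask)) <= {UNLABELLED, 2}

    def test_colour_jitter_leaves_mask_untouched(self, rng):
        img = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        mask = rng.integers(0, 3, (16, 16))
        _, out_mask = training.augment_frame(img, mask, np.random.default_rng(1),
                                             geometric=False, colour=True)
        assert np.array_equal(out_mask, mask)


def _fast_cfg(seed=0, epochs=1):
    return TrainConfig(batch_size=16, epochs=epochs, samples_per_class=8,
                       seed=seed, augment_geometric=False, augment_colour=False,
                       tcn_epochs=2)


def _tiny_cfg(seed=0):
    return enc.EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                             input_size=(64, 48), base_width=4, seed=seed)


class TestEncoderTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            training.train_encoder([], _tiny_cfg(), _fast_cfg())

    def test_training_without_masks_logs_zero_scene_loss(self, small_records):
        train, _ = small_records
        no_masks = [training.VideoRecord(v.video_id, v.frames, v.phase_labels,
                                         {}, None) for v in train[:3]]
        _, log = training.train_encoder(no_masks, _tiny_cfg(), _fast_cfg())
        assert all(rec["L_S"] == 0.0 for rec in log)

    def test_checkpoint_reload_reproduces_forward(self, small_records, tmp_path,
                                                  rng):
        train, _ = small_records
        model, _ = training.train_encoder(train[:3], _tiny_cfg(), _fast_cfg())
        img = rng.integers(0, 256, (48, 64, 3), dtype=np.uint8)
        before = model.forward(img)["phase"].data
        enc.save_encoder(model, tmp_path / "ck.npz")
        after = enc.load_encoder(tmp_path / "ck.npz").eval().forward(img)["phase"].data
        assert np.array_equal(before, after)


class TestTwoStage:
    @pytest.fixture(scope="class")
    def run(self, small_records, tmp_path_factory):
        train, test = small_records
        out = tmp_path_factory.mktemp("preds")
        tcn_cfg = TCNConfig(input_dim=_tiny_cfg().branch_channels, num_phases=5,
                            num_stages=2, layers_per_stage=3, hidden_channels=8,
                            seed=0)
        result = training.run_two_stage(train[:4], test[:2], _tiny_cfg(),
                                        tcn_cfg, _fast_cfg(), out_dir=out)
        return result, train[:4], test[:2], out

    def test_one_prediction_row_per_frame(self, run):
        result, train, test, out = run
        for v in train + test:
            ids, probs = result["predictions"][v.video_id]
            assert len(ids) == v.num_frames
            assert probs.shape == (v.num_frames, 5)
        for v in test:
            lines = (out / f"{v.video_id}.tsv").read_text().strip().splitlines()
            assert len(lines) == v.num_frames + 1  # header

    def test_encoder_frozen_during_temporal_stage(self, small_records):
        train, test = small_records
        model, _ = training.train_encoder(train[:3], _tiny_cfg(), _fast_cfg())
        before = {n: p.data.copy() for n, p in model.named_parameters()}
        feats = training.extract_features(model, train[:3])
        labels = {v.video_id: v.phase_labels for v in train[:3]}
        training.train_tcn(feats, labels,
                           TCNConfig(input_dim=_tiny_cfg().branch_channels,
                                     num_phases=5, layers_per_stage=2,
                                     hidden_channels=4), _fast_cfg())
        for n, p in model.named_parameters():
            assert np.array_equal(before[n], p.data), n


class TestFolds:
    def test_pinned_videos_always_in_training(self):
        ids = [f"v{i}" for i in range(10)]
        pinned = {"v0", "v1", "v2"}
        folds = training.make_cv_folds(ids, n_folds=5, n_test=3, pinned=pinned,
                                       seed=0)
        assert len(folds) == 5
        for train_ids, test_ids in folds:
            assert pinned <= set(train_ids)
            assert len(test_ids) == 3
            assert set(train_ids) | set(test_ids) == set(ids)

    def test_too_few_free_videos_rejected(self):
        with pytest.raises(ValueError):
            training.make_cv_folds(["a", "b"], 1, 2, {"a"}, seed=0)
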