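"""Loss oracles: closed-form cross-entropy values, sparse-mask exclusion
semantics, and the truncated temporal MSE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surgphase.autodiff as ad
from surgphase import losses
from surgphase.losses import (UNLABELLED, ClampSpec, clamp, encoder_loss,
                              instrument_loss, phase_loss, scene_loss, tcn_loss)

RNG = np.random.default_rng(42)


class TestPhaseLoss:
    def test_uniform_prediction_gives_log_P(self):
        pred = np.full((1, 7), 1 / 7)
        assert np.isclose(float(phase_loss(pred, [3]).data), np.log(7), atol=1e-9)

    def test_correct_one_hot_gives_zero(self):
        pred = np.eye(4)[[2]]
        assert float(phase_loss(pred, [2]).data) < 1e-9

    def test_batch_mean_matches_per_frame_oracle(self):
        pred = ad.softmax(ad.Tensor(RNG.normal(size=(5, 4))), axis=1).data
        ann = RNG.integers(0, 4, 5)
        expect = np.mean([-np.log(pred[i, ann[i]]) for i in range(5)])
        assert np.isclose(float(phase_loss(pred, ann).data), expect, atol=1e-9)

    def test_out_of_range_class_rejected(self):
        with pytest.raises(ValueError):
            phase_loss(np.full((1, 3), 1 / 3), [3])

    def test_batch_order_invariance(self):
        pred = ad.softmax(ad.Tensor(RNG.normal(size=(6, 3))), axis=1).data
        ann = RNG.integers(0, 3, 6)
        perm = RNG.permutation(6)
        a = float(phase_loss(pred, ann).data)
        b = float(phase_loss(pred[perm], ann[perm]).data)
        assert np.isclose(a, b, atol=1e-12)


class TestSceneLoss:
    def _seg(self, n=3, s=4, hw=(5, 5)):
        return ad.softmax(ad.Tensor(RNG.normal(size=(n, s) + hw),
                                    requires_grad=True), axis=1)

    def test_no_annotated_frames_gives_exact_zero(self):
        seg = self._seg()
        masks = RNG.integers(0, 4, (3, 5, 5))
        out = scene_loss(seg, masks, np.zeros(3, bool))
        assert float(out.data) == 0.0
        assert out._parents == ()  # constant: no gradient flows anywhere

    def test_perfect_one_hot_prediction_gives_zero(self):
        mask = RNG.integers(0, 4, (1, 5, 5))
        logits = np.full((1, 4, 5, 5), -300.0)
        for i in range(5):
            for j in range(5):
                logits[0, mask[0, i, j], i, j] = 300.0
        seg = ad.softmax(ad.Tensor(logits), axis=1)
        assert float(scene_loss(seg, mask, [True]).data) < 1e-6

    def test_unannotated_mask_bytes_do_not_affect_loss(self):
        seg = self._seg(n=2)
        masks = RNG.integers(0, 4, (2, 5, 5))
        l_ref = float(scene_loss(seg, masks, [True, False]).data)
        garbage = masks.copy()
        garbage[1] = RNG.integers(0, 4, (5, 5))
        l_garbage = float(scene_loss(seg, garbage, [True, False]).data)
        solo = float(scene_loss(ad.take(seg, [0], axis=0), masks[:1], [True]).data)
        assert l_ref == l_garbage  # bitwise
        assert np.isclose(l_ref, solo, atol=1e-12)

    def test_unlabelled_pixels_excluded_from_mean(self):
        seg = self._seg(n=1)
        mask = RNG.integers(0, 4, (1, 5, 5))
        mask[0, :2] = UNLABELLED
        expect = np.mean([-np.log(seg.data[0, mask[0, i, j], i, j])
                          for i in range(5) for j in range(5)
                          if mask[0, i, j] != UNLABELLED])
        assert np.isclose(float(scene_loss(seg, mask, [True]).data), expect,
                          atol=1e-9)

    def test_invalid_class_on_annotated_pixel_rejected(self):
        seg = self._seg(n=1)
        mask = np.full((1, 5, 5), 7)
        with pytest.raises(ValueError):
            scene_loss(seg, mask, [True])


class TestEncoderLoss:
    @pytest.mark.parametrize("scene,phase,instr,expect", [
        (0.5, 1.0, None, 1.5), (0.0, 2.25, None, 2.25), (0.5, 1.0, 0.25, 1.75),
    ])
    def test_unweighted_sum(self, scene, phase, instr, expect):
        out = encoder_loss(scene, phase, instr)
        assert np.isclose(float(out.data), expect)


class TestClamp:
    @pytest.mark.parametrize("x,expect", [(6.0, 4.0), (-2.0, 0.0), (3.5, 3.5)])
    def test_bounds_at_c_4(self, x, expect):
        assert clamp(np.array([x]), ClampSpec(4.0))[0] == expect

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-10, 10), st.floats(0.1, 8))
    def test_idempotence(self, x, c):
        spec = ClampSpec(c)
        once = clamp(np.array([x]), spec)
        assert np.array_equal(clamp(once, spec), once)

    def test_invalid_c_rejected(self):
        with pytest.raises(ValueError):
            ClampSpec(0.0)


class TestTCNLoss:
    def test_hand_example_ce_plus_truncated_mse(self):
        out = tcn_loss([np.array([[0.5, 0.5]])], [0], ClampSpec(4.0))
        assert np.isclose(float(out.data), np.log(2) + 0.125, atol=1e-6)

    def test_perfect_predictions_give_zero(self):
        pred = np.eye(3)[[0, 1, 2, 2]]
        out = tcn_loss([pred, pred], [0, 1, 2, 2], ClampSpec(4.0))
        assert float(out.data) < 1e-6

    def test_stage_sum_linearity(self):
        pred = ad.softmax(ad.Tensor(RNG.normal(size=(6, 3))), axis=1).data
        ann = RNG.integers(0, 3, 6)
        one = float(tcn_loss([pred], ann).data)
        two = float(tcn_loss([pred, pred], ann).data)
        assert np.isclose(two, 2 * one, atol=1e-9)

    def test_loss_is_at_least_the_cross_entropy(self):
        pred = ad.softmax(ad.Tensor(RNG.normal(size=(8, 4))), axis=1).data
        ann = RNG.integers(0, 4, 8)
        total = float(tcn_loss([pred], ann).data)
        ce = np.mean([-np.log(pred[t, ann[t]]) for t in range(8)])
        assert total >= ce - 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tcn_loss([np.full((3, 2), 0.5)], [0, 1])

    @pytest.mark.parametrize("variant", ["square_then_clamp", "smooth_logprob"])
    def test_alternative_variants_run_and_vanish_at_perfection(self, variant):
        pred = np.eye(2)[[0, 0, 1]]
        out = tcn_loss([pred], [0, 0, 1], variant=variant)
        assert float(out.data) < 1e-6 or variant == "smooth_logprob"

    def test_batch_order_invariance(self):
        pred = ad.softmax(ad.Tensor(RNG.normal(size=(5, 3))), axis=1).data
        ann = RNG.integers(0, 3, 5)
        perm = RNG.permutation(5)
        a = float(tcn_loss([pred], ann).data)
        b = float(tcn_loss([pred[perm]], ann[perm]).data)
        assert np.isclose(a, b, atol=1e-12)


class TestInstrumentLoss:
    def test_matches_binary_cross_entropy_oracle(self):
        p = 1 / (1 + np.exp(-RNG.normal(size=(4, 3))))
        y = RNG.integers(0, 2, (4, 3)).astype(float)
        expect = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert np.isclose(float(instrument_loss(p, y).data), expect, atol=1e-6)


def test_scene_loss_gradients_are_zero_without_annotations(tiny_encoder, rng):
    """With no annotated frame, the joint loss gradient equals the phase-only
    gradient bitwise: the scene term contributes nothing."""
    from surgphase.training import _encoder_step
    img = rng.integers(0, 256, (2, 48, 64, 3), dtype=np.uint8)
    masks = np.full((2, 48, 64), UNLABELLED)
    ann = np.zeros(2, bool)
    labels = np.array([1, 3])
    tiny_encoder.train()
    total, l_s, _, _ = _encoder_step(tiny_encoder, img, masks, ann, labels,
                                     None, phase_only=False)
    assert l_s == 0.0
    tiny_encoder.zero_grad()
    total.backward()
    g_joint = {n: p.grad.copy() if p.grad is not None else None
               for n, p in tiny_encoder.named_parameters()}
    tiny_encoder.zero_grad()
    total2, _, _, _ = _encoder_step(tiny_encoder, img, masks, ann, labels,
                                    None, phase_only=True)
    total2.backward()
    for n, p in tiny_encoder.named_parameters():
        if p.grad is None:
            assert g_joint[n] is None
        else:
            assert np.array_equal(g_joint[n], p.grad), n
    tiny_encoder.zero_grad()
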