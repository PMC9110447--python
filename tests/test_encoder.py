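"""Multi-task encoder: construction contracts, fusion arithmetic, branch
forwards and feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surgphase.autodiff as ad
from surgphase import encoder as enc
from surgphase.encoder import (EncoderConfig, FusionWeights,
                               fast_norm_coefficients, fuse_concat_conv,
                               fuse_fast_normalized)


def _image(rng, w=64, h=48, n=None):
    shape = (h, w, 3) if n is None else (n, h, w, 3)
    return rng.integers(0, 256, shape, dtype=np.uint8)


class TestBuild:
    def test_depth50_branch_channels_are_2048(self):
        cfg = EncoderConfig(backbone_depth=50, num_phases=7, num_scene_classes=13)
        assert cfg.branch_channels == 2048
        assert cfg.num_branches == 2

    def test_depth18_smoke_forward(self, tiny_encoder, rng):
        out = tiny_encoder.forward(_image(rng))
        assert out["phase"].data.shape == (1, 5)
        assert out["seg"].data.shape == (1, 6, 48, 64)
        assert tiny_encoder.num_parameters() > 0

    @pytest.mark.parametrize("bad", [
        {"backbone_depth": 34}, {"fusion_kind": "bogus"}, {"num_phases": 1},
        {"num_scene_classes": 1}, {"input_size": (16, 48)},
    ])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ValueError):
            enc.build_encoder(EncoderConfig(base_width=4, **bad))

    def test_instrument_branch_presence_follows_config(self, tiny_config):
        assert enc.build_encoder(tiny_config).instrument_head is None
        cfg3 = EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                             num_instruments=3, input_size=(64, 48), base_width=4)
        model3 = enc.build_encoder(cfg3)
        assert model3.instrument_head is not None
        assert cfg3.num_branches == 3


class TestSceneBranch:
    def test_segmentation_is_pixelwise_distribution_at_input_resolution(
            self, tiny_encoder, rng):
        f_s, seg = enc.forward_scene(tiny_encoder, _image(rng))
        assert seg.data.shape == (1, 6, 48, 64)
        assert np.allclose(seg.data.sum(axis=1), 1.0, atol=1e-5)

    def test_channel_reduction_is_four_fold(self, tiny_encoder, tiny_config):
        cb = tiny_config.branch_channels
        conv3 = tiny_encoder.scene_module.conv3
        assert conv3.weight.data.shape[:2] == (cb // 4, cb)
        conv1 = tiny_encoder.scene_module.conv1
        assert conv1.weight.data.shape[:2] == (6, cb // 4)

    def test_depth50_channel_sequence_2048_512_S(self):
        cfg = EncoderConfig(backbone_depth=50, num_phases=7, num_scene_classes=13)
        model = enc.build_encoder(cfg)
        assert model.scene_module.conv3.weight.data.shape[:2] == (512, 2048)
        assert model.scene_module.conv1.weight.data.shape[:2] == (13, 512)

    def test_output_resolution_follows_input_not_stride_arithmetic(self, rng):
        # 100x76 is not divisible by 32; the final upscale must restore it
        cfg = EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                            input_size=(100, 76), base_width=4)
        model = enc.build_encoder(cfg)
        _, seg = enc.forward_scene(model, _image(rng, w=100, h=76))
        assert seg.data.shape[-2:] == (76, 100)


class TestFastNormFusion:
    def test_single_branch_limit(self, rng):
        f_s, f_p = rng.normal(size=(2, 3, 4, 4))
        out = fuse_fast_normalized([f_s, f_p], FusionWeights([1.0, 0.0], 1e-4))
        assert np.allclose(out, f_s / 1.0001, atol=1e-12)

    def test_equal_weights_hand_value(self, rng):
        v = rng.normal(size=(3, 4))
        out = fuse_fast_normalized([v, v], FusionWeights([1.0, 1.0], 1e-4))
        assert np.allclose(out, (2.0 / 2.0001) * v, atol=1e-12)

    def test_all_negative_alphas_give_zero_map(self, rng):
        fs = [rng.normal(size=(2, 2)) for _ in range(2)]
        out = fuse_fast_normalized(fs, FusionWeights([-3.0, -1.0], 1e-4))
        assert np.allclose(out, 0.0)

    def test_errors_on_empty_and_mismatched_inputs(self):
        with pytest.raises(ValueError):
            fuse_fast_normalized([], FusionWeights([], 1e-4))
        with pytest.raises(ValueError):
            fuse_fast_normalized([np.ones((2, 2)), np.ones((3, 2))],
                                 FusionWeights([1.0, 1.0]))
        with pytest.raises(ValueError):
            fuse_fast_normalized([np.ones((2, 2))], FusionWeights([1.0, 1.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=4))
    def test_coefficients_nonnegative_and_sum_below_one(self, alphas):
        coeff = fast_norm_coefficients(alphas, 1e-4)
        assert (coeff >= 0).all()
        assert coeff.sum() < 1.0
        a = np.maximum(alphas, 0.0).sum()
        assert np.isclose(coeff.sum(), a / (a + 1e-4))

    def test_permutation_consistency(self, rng):
        f1, f2 = rng.normal(size=(2, 2, 3))
        a = fuse_fast_normalized([f1, f2], FusionWeights([0.7, 2.0]))
        b = fuse_fast_normalized([f2, f1], FusionWeights([2.0, 0.7]))
        assert np.allclose(a, b, atol=1e-12)


class TestConcatConvFusion:
    @pytest.mark.parametrize("variant", ["a", "b"])
    def test_output_shape_matches_branch_shape(self, variant, rng):
        fus = enc.ConcatConvFusion(2, 8, variant, rng=np.random.default_rng(0))
        feats = [ad.Tensor(rng.normal(size=(2, 8, 3, 3))) for _ in range(2)]
        out = fus(feats)
        assert out.data.shape == (2, 8, 3, 3)

    @pytest.mark.parametrize("variant", ["a", "b"])
    def test_three_branch_inputs_accepted(self, variant, rng):
        fus = enc.ConcatConvFusion(3, 4, variant, rng=np.random.default_rng(0))
        feats = [ad.Tensor(rng.normal(size=(1, 4, 2, 2))) for _ in range(3)]
        assert fus(feats).data.shape == (1, 4, 2, 2)

    def test_skip_passthrough_when_fusion_zeroed(self, rng):
        fus = enc.ConcatConvFusion(2, 4, "a", rng=np.random.default_rng(0))
        fus.conv.weight.data[:] = 0.0
        fus.bn.beta.data[:] = 0.0
        fus.eval()
        f_p = ad.Tensor(rng.normal(size=(1, 4, 2, 2)))
        feats = [ad.Tensor(rng.normal(size=(1, 4, 2, 2))), f_p]
        out = fuse_concat_conv(feats, fus, use_skip=True, phase_feature=f_p)
        assert np.allclose(out.data, f_p.data, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        fus = enc.ConcatConvFusion(2, 4, "a", rng=np.random.default_rng(0))
        with pytest.raises(ValueError):
            fus([ad.Tensor(np.ones((1, 4, 2, 2))), ad.Tensor(np.ones((1, 4, 3, 2)))])


class TestPhaseBranch:
    def test_phase_output_is_distribution_of_length_P(self, tiny_encoder, rng):
        out = tiny_encoder.forward(_image(rng, n=3))
        assert out["phase"].data.shape == (3, 5)
        assert np.allclose(out["phase"].data.sum(axis=1), 1.0, atol=1e-5)

    def test_zeroed_scene_alpha_reduces_to_single_task_forward(self, rng):
        cfg = EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                            input_size=(64, 48), base_width=4, seed=3)
        model = enc.build_encoder(cfg).eval()
        model.fusion.alphas[0].data = np.asarray(0.0)  # alpha_S
        model.fusion.alphas[1].data = np.asarray(1.0)  # alpha_P
        img = _image(rng)
        multi = model.forward(img, with_scene=True)["phase"].data
        single = model.forward(img, with_scene=False)["phase"].data
        assert np.allclose(multi, single, atol=1e-5)

    def test_missing_instrument_feature_rejected(self, rng):
        cfg = EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                            num_instruments=2, input_size=(64, 48), base_width=4)
        model = enc.build_encoder(cfg)
        x = model.preprocess(_image(rng))
        f_b = model.forward_backbone(x)
        f_s = model.scene_head(f_b)
        with pytest.raises(ValueError):
            model.forward_phase(f_b, f_s, None)


class TestInstrumentBranch:
    def test_presence_probabilities_and_shape_compatibility(self, rng):
        cfg = EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                            num_instruments=7, input_size=(64, 48), base_width=4)
        model = enc.build_encoder(cfg)
        out = model.forward(_image(rng))
        pres = out["instrument"].data
        assert pres.shape == (1, 7)
        assert ((pres >= 0) & (pres <= 1)).all()
        assert out["f_I"].data.shape == out["f_S"].data.shape

    def test_disabled_branch_raises(self, tiny_encoder, rng):
        x = tiny_encoder.preprocess(_image(rng))
        f_b = tiny_encoder.forward_backbone(x)
        with pytest.raises(ValueError):
            tiny_encoder.forward_instrument(f_b)


class TestFeatureExtraction:
    def test_feature_length_matches_branch_channels(self, tiny_encoder,
                                                    tiny_config, rng):
        feat = enc.extract_frame_feature(tiny_encoder.eval(), _image(rng))
        assert feat.shape == (tiny_config.branch_channels,)

    def test_deterministic_in_eval_mode(self, tiny_encoder, rng):
        img = _image(rng)
        tiny_encoder.eval()
        f1 = enc.extract_frame_feature(tiny_encoder, img)
        f2 = enc.extract_frame_feature(tiny_encoder, img)
        assert np.array_equal(f1, f2)

    def test_invariant_to_discarded_fc_weights(self, rng):
        cfg = EncoderConfig(backbone_depth=18, num_phases=5, num_scene_classes=6,
                            input_size=(64, 48), base_width=4, seed=5)
        model = enc.build_encoder(cfg).eval()
        img = _image(rng)
        f1 = enc.extract_frame_feature(model, img)
        model.fc.weight.data = np.zeros_like(model.fc.weight.data)
        model.fc.bias.data = np.zeros_like(model.fc.bias.data)
        f2 = enc.extract_frame_feature(model, img)
        assert np.array_equal(f1, f2)

    def test_gap_of_constant_map_is_that_constant(self):
        x = ad.Tensor(np.full((1, 4, 3, 5), 2.5))
        assert np.allclose(ad.global_avg_pool(x).data, 2.5)


def test_checkpoint_round_trip(tmp_path, tiny_encoder, rng):
    img = _image(rng)
    tiny_encoder.eval()
    before = tiny_encoder.forward(img)["phase"].data
    enc.save_encoder(tiny_encoder, tmp_path / "enc.npz")
    reloaded = enc.load_encoder(tmp_path / "enc.npz").eval()
    after = reloaded.forward(img)["phase"].data
    assert np.array_equal(before, after)
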