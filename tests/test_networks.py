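import time

import numpy as np
import pytest

from symseg_da.autodiff import Tensor, no_grad
from symseg_da.networks import (
    FeatureDiscriminator,
    HybridAttentionBlock,
    ModelBundle,
    NetworkConfig,
    PixelDiscriminator,
    Segmenter,
    Translator,
    build_bundle,
    discriminate_feature,
    discriminate_pixel,
    encode_bottleneck,
    segment_probs,
    translate,
)
from symseg_da.phantom import DomainStyle, apply_domain_style


@pytest.fixture(scope="module")
def bundle():
    return build_bundle("tiny", seed=42, translator_width=8, segmenter_width=8,
                        discriminator_width=8)


@pytest.fixture(scope="module")
def image64():
    return np.random.default_rng(0).uniform(0, 1, (64, 64)).astype(np.float32)


class TestTranslator:
    def test_shape_contract(self, bundle, image64):
        out = translate(bundle.g_s2t, image64)
        assert out.shape == (64, 64)

    def test_range_contract(self, bundle, image64):
        out = translate(bundle.g_s2t, image64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_bad_size_names_constraint(self, bundle):
        with pytest.raises(ValueError, match="divisible by 4"):
            translate(bundle.g_s2t, np.zeros((30, 30), np.float32))

    def test_gradient_matches_finite_difference(self):
        t = Translator(base_width=4, n_res=1, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).uniform(0, 1, (1, 1, 16, 16)).astype(np.float32))
        param = t.decoder.layers[-2].bias  # output conv bias, scalar-ish gradient
        loss = t(x).mean()
        loss.backward()
        autodiff = float(param.grad[0])
        eps = 1e-2
        param.data[0] += eps
        with no_grad():
            up = float(t(x).mean().data)
        param.data[0] -= 2 * eps
        with no_grad():
            down = float(t(x).mean().data)
        param.data[0] += eps
        numeric = (up - down) / (2 * eps)
        assert abs(autodiff - numeric) / max(abs(numeric), 1e-8) < 1e-3

    def test_symmetry_of_pair(self, bundle):
        s1 = bundle.g_s2t.state_dict()
        s2 = bundle.g_t2s.state_dict()
        assert set(s1) == set(s2)
        assert all(s1[k].shape == s2[k].shape for k in s1)
        assert any(not np.array_equal(s1[k], s2[k]) for k in s1)  # independent params


class TestSegmenter:
    def test_probability_range(self, bundle, image64):
        probs = segment_probs(bundle.f_s, image64)
        assert probs.shape == (64, 64)
        assert probs.min() > 0.0 and probs.max() < 1.0

    def test_constant_input_near_constant_output(self, bundle):
        probs = segment_probs(bundle.f_s, np.full((64, 64), 0.5, np.float32))
        assert probs.max() - probs.min() < 0.5

    def test_bad_size_names_constraint(self, bundle):
        with pytest.raises(ValueError, match="divisible by 16"):
            segment_probs(bundle.f_s, np.zeros((24, 24), np.float32))

    def test_bottleneck_shape(self, bundle, image64):
        feats = encode_bottleneck(bundle.f_s, image64)
        assert feats.shape == (1, 8 * bundle.f_s.base_width, 4, 4)

    def test_eval_determinism(self, bundle, image64):
        f1 = encode_bottleneck(bundle.f_s, image64)
        f2 = encode_bottleneck(bundle.f_s, image64)
        assert np.array_equal(f1, f2)

    def test_style_shift_moves_features(self, bundle, image64):
        styled = apply_domain_style(image64, DomainStyle(gamma=1.6, invert=True),
                                    np.random.default_rng(0))
        f1 = encode_bottleneck(bundle.f_s, image64)
        f2 = encode_bottleneck(bundle.f_s, styled)
        assert np.abs(f1 - f2).mean() > 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            Segmenter(mode="resnet")

    def test_efficientnet_mode_forward(self):
        f = Segmenter(mode="efficientnet-b0", rng=np.random.default_rng(0))
        x = np.random.default_rng(1).uniform(0, 1, (32, 32)).astype(np.float32)
        probs = segment_probs(f, x)
        assert probs.shape == (32, 32)
        feats = encode_bottleneck(f, x)
        assert feats.shape == (1, 112, 2, 2)


class TestHybridAttention:
    def test_output_is_sum_of_branches(self):
        block = HybridAttentionBlock(8, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(1).normal(0, 1, (2, 8, 6, 6)).astype(np.float32))
        cg, sg = block.forward_parts(x)
        out = block(x)
        assert np.allclose(out.data, cg.data + sg.data, atol=1e-6)

    def test_gate_override_degenerations(self):
        block = HybridAttentionBlock(4, rng=np.random.default_rng(0))
        x = Tensor(np.random.default_rng(2).normal(0, 1, (1, 4, 5, 5)).astype(np.float32))
        block.gate_override = 1.0
        assert np.allclose(block(x).data, 2.0 * x.data, atol=1e-6)
        block.gate_override = 0.0
        assert np.allclose(block(x).data, 0.0, atol=1e-6)

    def test_shape_preserved(self):
        block = HybridAttentionBlock(8, rng=np.random.default_rng(0))
        x = Tensor(np.zeros((3, 8, 7, 7), np.float32))
        assert block(x).shape == x.shape


class TestDiscriminators:
    def test_pixel_scores_in_unit_interval(self, bundle, image64):
        scores = discriminate_pixel(bundle.d_s_pix, image64)
        assert scores.min() > 0.0 and scores.max() < 1.0

    def test_patch_map_arithmetic(self, bundle, image64):
        scores = discriminate_pixel(bundle.d_s_pix, image64)
        assert scores.shape == (1, 1, 8, 8)

    def test_feature_scores(self, bundle, image64):
        feats = encode_bottleneck(bundle.f_s, image64)
        scores = discriminate_feature(bundle.d_s_feat, feats)
        assert scores.min() > 0.0 and scores.max() < 1.0

    def test_wrong_channels_rejected(self, bundle):
        with pytest.raises(ValueError, match="channels"):
            bundle.d_s_feat(Tensor(np.zeros((1, 3, 4, 4), np.float32)))


class TestBundle:
    def test_checkpoint_roundtrip_bitwise(self, bundle, image64, tmp_path):
        path = tmp_path / "ckpt.npz"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        for name in ModelBundle.NET_NAMES:
            a = getattr(bundle, name).state_dict()
            b = getattr(loaded, name).state_dict()
            assert set(a) == set(b)
            for k in a:
                assert np.array_equal(a[k], b[k]), (name, k)
        assert np.array_equal(segment_probs(loaded.f_s, image64),
                              segment_probs(bundle.f_s, image64))

    def test_mismatched_architecture_refused(self, bundle, tmp_path):
        path = tmp_path / "ckpt.npz"
        bundle.save(path)
        other = build_bundle("tiny", seed=0)  # default width 16 != 8
        with pytest.raises(ValueError, match="does not match"):
            other.load_into(path)

    def test_families_symmetric(self, bundle):
        for a, b in (("f_s", "f_t"), ("d_s_pix", "d_t_pix"), ("d_s_feat", "d_t_feat")):
            sa = getattr(bundle, a).state_dict()
            sb = getattr(bundle, b).state_dict()
            assert set(sa) == set(sb)
            assert all(sa[k].shape == sb[k].shape for k in sa)

    def test_forward_backward_under_one_second(self, bundle):
        x = Tensor(np.random.default_rng(0).uniform(0, 1, (1, 1, 64, 64)).astype(np.float32))
        for net in (bundle.g_s2t, bundle.f_s):
            start = time.perf_counter()
            net.zero_grad()
            net(x).mean().backward()
            assert time.perf_counter() - start < 1.0

    def test_parameter_hash_detects_change(self, bundle):
        h1 = bundle.parameter_hash(["f_s"])["f_s"]
        p = bundle.f_s.parameters()[0]
        p.data = p.data + 1e-3
        h2 = bundle.parameter_hash(["f_s"])["f_s"]
        p.data = p.data - 1e-3
        assert h1 != h2
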