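"""Structural re-parameterization: fusion equivalence and oracles."""

import copy

import numpy as np
import pytest

from smokeformer.encoder import EncoderConfig, MultiBranchMixer
from smokeformer.head import ModelConfig, SmokeClassifier
from smokeformer.reparam import (FusedMixer, FusedParams, deploy_model,
                                 dirac_kernel, embed_kernel, fold_norm,
                                 fuse_block, fuse_mixer)
from smokeformer.layers import BatchNorm2d, DepthwiseConv2d


def brute_force_depthwise(x, kernel, bias):
    """Direct-summation depthwise convolution with zero 'same' padding.

    Written independently of the production conv path: explicit Python
    loops over every output pixel and kernel tap, in float64.
    """
    b, c, h, w = x.shape
    _, k, _ = kernel.shape
    p = k // 2
    out = np.zeros((b, c, h, w), dtype=np.float64)
    for bi in range(b):
        for ci in range(c):
            for i in range(h):
                for j in range(w):
                    acc = 0.0
                    for ki in range(k):
                        for kj in range(k):
                            ii, jj = i + ki - p, j + kj - p
                            if 0 <= ii < h and 0 <= jj < w:
                                acc += kernel[ci, ki, kj] * x[bi, ci, ii, jj]
                    out[bi, ci, i, j] = acc + bias[ci]
    return out


def randomize_mixer(mixer: MultiBranchMixer, rng) -> None:
    """Give every branch non-trivial weights and frozen norm statistics.

    Kernels stay at He scale (as in any initialized or trained network) so
    activations are O(1); the normalization statistics are fully random.
    """
    for branch in mixer.branches:
        conv, norm = branch.layers
        k = conv.kernel_size
        conv.weight[...] = rng.standard_normal(conv.weight.shape) * np.sqrt(2.0 / k**2)
        norm.running_mean[...] = rng.standard_normal(norm.running_mean.shape)
        norm.running_var[...] = rng.uniform(0.3, 2.0, norm.running_var.shape)
        norm.gamma[...] = rng.uniform(0.5, 1.5, norm.gamma.shape)
        norm.beta[...] = rng.standard_normal(norm.beta.shape)
    mixer.eval()


class TestFoldNorm:
    def test_identity_norm_leaves_kernel(self, rng):
        k = rng.standard_normal((4, 3, 3))
        k2, b2 = fold_norm(k, np.zeros(4), np.ones(4), np.ones(4), np.zeros(4), 0.0)
        np.testing.assert_allclose(k2, k)
        np.testing.assert_allclose(b2, 0)

    def test_zero_gamma_silences_branch(self, rng):
        k = rng.standard_normal((4, 3, 3))
        beta = rng.standard_normal(4)
        k2, b2 = fold_norm(k, rng.standard_normal(4), np.ones(4),
                           np.zeros(4), beta, 1e-5)
        np.testing.assert_allclose(k2, 0)
        np.testing.assert_allclose(b2, beta)

    def test_fold_matches_norm_of_conv(self, rng):
        """conv(x, k') + b' == batchnorm(conv(x, k)) in inference mode."""
        conv = DepthwiseConv2d(3, 3, rng=rng)
        norm = BatchNorm2d(3)
        norm.running_mean[...] = rng.standard_normal(3)
        norm.running_var[...] = rng.uniform(0.3, 2.0, 3)
        norm.gamma[...] = rng.uniform(0.5, 1.5, 3)
        norm.beta[...] = rng.standard_normal(3)
        norm.eval()
        k2, b2 = fold_norm(conv.weight, norm.running_mean, norm.running_var,
                           norm.gamma, norm.beta, norm.eps)
        fused = FusedMixer(FusedParams(kernel=k2.astype(np.float32),
                                       bias=b2.astype(np.float32)))
        for _ in range(10):
            x = rng.standard_normal((2, 3, 6, 6)).astype(np.float32)
            np.testing.assert_allclose(fused(x), norm(conv(x)), atol=1e-6, rtol=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fold_norm(np.ones((1, 3, 3)), np.zeros(1), np.array([-1e-5]),
                      np.ones(1), np.zeros(1), 0.0)


class TestEmbedKernel:
    def test_3x3_centred_in_7x7(self, rng):
        k = rng.standard_normal((2, 3, 3))
        out = embed_kernel(k, 7)
        np.testing.assert_array_equal(out[:, 2:5, 2:5], k)
        out[:, 2:5, 2:5] = 0
        assert not out.any()

    def test_identity_maps_to_dirac(self):
        d = dirac_kernel(3, 7)
        assert d[0, 3, 3] == 1.0 and d.sum() == 3.0

    def test_same_size_unchanged(self, rng):
        k = rng.standard_normal((1, 5, 5))
        assert embed_kernel(k, 5) is k

    @pytest.mark.parametrize("k,target", [(3, 4), (3, 2), (2, 5)])
    def test_parity_and_size_violations(self, k, target):
        with pytest.raises(ValueError):
            embed_kernel(np.zeros((1, k, k)), target)


class TestFuseMixer:
    def test_identity_branch_only_gives_dirac(self, rng):
        mixer = MultiBranchMixer(3, (3,), include_identity=True, rng=rng)
        mixer.eval()
        for branch in mixer.branches:
            branch.layers[0].weight[...] = 0
            branch.layers[1].gamma[...] = 0  # silence the conv branch entirely
            branch.layers[1].beta[...] = 0
        fused = fuse_mixer(mixer)
        np.testing.assert_allclose(fused.kernel, dirac_kernel(3, 3), atol=1e-7)
        np.testing.assert_allclose(fused.bias, 0, atol=1e-7)
        x = rng.standard_normal((1, 3, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(FusedMixer(fused)(x), x, atol=1e-6)

    @pytest.mark.parametrize("channels", [4, 16, 64])
    def test_block_level_equivalence(self, channels):
        """Multi-branch vs fused outputs agree within 1e-5 (float32)."""
        rng = np.random.default_rng(channels)
        mixer = MultiBranchMixer(channels, (7, 3), include_identity=True, rng=rng)
        randomize_mixer(mixer, rng)
        fused = FusedMixer(fuse_mixer(mixer))
        for _ in range(10):
            x = rng.standard_normal((2, channels, 9, 9)).astype(np.float32)
            assert np.abs(mixer(x) - fused(x)).max() <= 1e-5

    def test_brute_force_oracle_float64(self):
        """Fused conv matches the independent direct-summation convolution
        exactly (1e-10, float64) on 1-channel 5x5 inputs."""
        rng = np.random.default_rng(42)
        mixer = MultiBranchMixer(1, (5, 3), include_identity=True, rng=rng)
        randomize_mixer(mixer, rng)
        fused = fuse_mixer(mixer)
        kernel = fused.kernel.astype(np.float64)
        bias = fused.bias.astype(np.float64)
        conv = DepthwiseConv2d(1, 5, bias=True)
        conv.weight[...] = fused.kernel
        conv.bias[...] = fused.bias
        for _ in range(5):
            x = rng.standard_normal((1, 1, 5, 5))
            oracle = brute_force_depthwise(x, kernel, bias)
            ours = np.zeros_like(oracle)
            # evaluate the production depthwise path in float64
            k = 5
            p = 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
            for ki in range(k):
                for kj in range(k):
                    ours += kernel[:, ki, kj][None, :, None, None] * \
                        xp[:, :, ki:ki + 5, kj:kj + 5]
            ours += bias[None, :, None, None]
            assert np.abs(ours - oracle).max() <= 1e-10

    def test_fusion_idempotent(self, rng):
        mixer = MultiBranchMixer(4, (5, 3), include_identity=True, rng=rng)
        randomize_mixer(mixer, rng)
        once = fuse_mixer(mixer)
        twice = fuse_mixer(FusedMixer(once))
        np.testing.assert_array_equal(once.kernel, twice.kernel)
        np.testing.assert_array_equal(once.bias, twice.bias)


class TestDeploy:
    @pytest.fixture
    def trained_pair(self, rng):
        model = SmokeClassifier(ModelConfig(input_size=32, embed_dim=16, depth=2, seed=5))
        # push batch statistics off their init values
        model.train(True)
        model(rng.random((8, 3, 32, 32)).astype(np.float32))
        model.eval()
        return model, deploy_model(model)

    def test_logit_agreement(self, rng, trained_pair):
        model, deployed = trained_pair
        for _ in range(10):
            x = rng.random((1, 3, 32, 32)).astype(np.float32)
            assert np.abs(model(x) - deployed(x)).max() <= 1e-4

    def test_label_agreement_on_100_images(self, rng, trained_pair):
        model, deployed = trained_pair
        x = rng.random((100, 3, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.predict_labels(x),
                                      deployed.predict_labels(x))

    def test_fused_has_fewer_mixer_parameters(self, trained_pair):
        model, deployed = trained_pair
        for a, b in zip(model.encoder.blocks, deployed.encoder.blocks):
            assert b.mixer.n_parameters() < a.mixer.n_parameters()

    def test_deploy_requires_eval_mode(self):
        model = SmokeClassifier(ModelConfig(input_size=32, embed_dim=8, depth=1))
        model.train(True)
        with pytest.raises(RuntimeError, match="inference mode"):
            deploy_model(model)

    def test_refuses_double_fusion(self, trained_pair):
        _, deployed = trained_pair
        with pytest.raises(RuntimeError, match="already fused"):
            deploy_model(deployed)

    def test_fuse_block_preserves_mlp(self, rng):
        cfg = EncoderConfig(depth=1, embed_dim=8, branch_kernel_sizes=(3,))
        from smokeformer.encoder import EncoderBlock
        block = EncoderBlock(cfg, rng=rng)
        block.eval()
        fused = fuse_block(block)
        np.testing.assert_array_equal(fused.fc1.weight, block.fc1.weight)
        assert isinstance(fused.mixer, FusedMixer)
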