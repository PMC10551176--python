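"""Structural re-parameterization: multi-branch mixer -> single depthwise conv.

At inference the batch-norm statistics are frozen, so each (depthwise conv ->
batch norm) branch is an affine function of its input and can be folded into
a single depthwise kernel plus bias.  Zero-padding the smaller kernels to the
largest branch size and summing, with the identity branch contributing a
centred Dirac kernel, yields one depthwise convolution that is exactly
equivalent (up to float rounding) to the trained multi-branch mixer — the
RepVGG construction applied to the ConvNeXt-style token mixer.

Fusion is available both as an in-memory model transform
(:func:`deploy_model`) and as a checkpoint-to-checkpoint transform via the
CLI.  Fused checkpoints are tagged so evaluation refuses to re-fuse them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .encoder import EncoderBlock, MultiBranchMixer
from .layers import BatchNorm2d, DepthwiseConv2d, Module

__all__ = [
    "FusedParams",
    "FusedMixer",
    "fold_norm",
    "embed_kernel",
    "fuse_mixer",
    "fuse_block",
    "deploy_model",
]

TOPOLOGY_MULTI_BRANCH = "multi_branch"
TOPOLOGY_FUSED = "fused"


@dataclass
class FusedParams:
    """Single-path equivalent of one multi-branch mixer."""

    kernel: np.ndarray  # (C, K, K), K = largest branch kernel size
    bias: np.ndarray    # (C,)


def fold_norm(kernel: np.ndarray, mean: np.ndarray, var: np.ndarray,
              gamma: np.ndarray, beta: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Fold frozen batch-norm statistics into a depthwise kernel.

    Returns ``(kernel', bias')`` with ``kernel' = kernel * gamma/sqrt(var+eps)``
    and ``bias' = beta - mean * gamma/sqrt(var+eps)``, so that
    ``conv(x, kernel') + bias' == norm(conv(x, kernel))`` in inference mode.
    """
    denom = np.asarray(var, dtype=np.float64) + eps
    if np.any(denom <= 0):
        raise ValueError("variance + eps must be positive in every channel")
    scale = np.asarray(gamma, dtype=np.float64) / np.sqrt(denom)
    kernel = np.asarray(kernel, dtype=np.float64) * scale[:, None, None]
    bias = np.asarray(beta, dtype=np.float64) - np.asarray(mean, dtype=np.float64) * scale
    return kernel, bias


def embed_kernel(kernel: np.ndarray, target_size: int) -> np.ndarray:
    """Centre a (C, k, k) depthwise kernel in a zero (C, K, K) frame."""
    k = kernel.shape[-1]
    if kernel.shape[-2] != k:
        raise ValueError("kernel must be square")
    if target_size < k:
        raise ValueError(f"target size {target_size} smaller than kernel {k}")
    if target_size % 2 == 0 or k % 2 == 0:
        raise ValueError("kernel sizes must be odd")
    if target_size == k:
        return kernel
    pad = (target_size - k) // 2
    out = np.zeros(kernel.shape[:-2] + (target_size, target_size), dtype=kernel.dtype)
    out[..., pad:pad + k, pad:pad + k] = kernel
    return out


def dirac_kernel(channels: int, size: int, dtype=np.float64) -> np.ndarray:
    """Depthwise identity kernel: 1 at the centre, 0 elsewhere."""
    out = np.zeros((channels, size, size), dtype=dtype)
    out[:, size // 2, size // 2] = 1.0
    return out


class FusedMixer(Module):
    """Single-path depthwise convolution replacing a multi-branch mixer."""

    def __init__(self, params: FusedParams) -> None:
        super().__init__()
        channels, k, _ = params.kernel.shape
        conv = DepthwiseConv2d(channels, k, bias=True)
        conv.weight[...] = params.kernel
        conv.bias[...] = params.bias
        self.add_module("conv", conv)
        self.channels = channels

    @property
    def fused_params(self) -> FusedParams:
        return FusedParams(kernel=self.conv.weight.copy(), bias=self.conv.bias.copy())

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.conv(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.conv.backward(grad)


def fuse_mixer(mixer: MultiBranchMixer | FusedMixer) -> FusedParams:
    """Collapse a multi-branch mixer to one depthwise kernel + bias.

    Fusing an already-fused mixer returns its parameters unchanged
    (idempotence).
    """
    if isinstance(mixer, FusedMixer):
        return mixer.fused_params
    sizes = [branch.layers[0].kernel_size for branch in mixer.branches]
    target = max(sizes)
    channels = mixer.channels
    kernel = np.zeros((channels, target, target), dtype=np.float64)
    bias = np.zeros(channels, dtype=np.float64)
    for branch in mixer.branches:
        conv: DepthwiseConv2d = branch.layers[0]
        norm: BatchNorm2d = branch.layers[1]
        k, b = fold_norm(conv.weight, norm.running_mean, norm.running_var,
                         norm.gamma, norm.beta, norm.eps)
        if conv.has_bias:
            b = b + np.asarray(conv.bias, dtype=np.float64) * (
                np.asarray(norm.gamma, dtype=np.float64)
                / np.sqrt(np.asarray(norm.running_var, dtype=np.float64) + norm.eps)
            )
        kernel += embed_kernel(k, target)
        bias += b
    if mixer.include_identity:
        kernel += dirac_kernel(channels, target)
    return FusedParams(kernel=kernel.astype(np.float32), bias=bias.astype(np.float32))


def fuse_block(block: EncoderBlock) -> EncoderBlock:
    """Return a copy of an encoder block with its mixer fused single-path."""
    fused = copy.deepcopy(block)
    params = fuse_mixer(block.mixer)
    mixer = FusedMixer(params)
    mixer.train(block.training)
    fused._modules["mixer"] = mixer
    fused.mixer = mixer
    return fused


def mixer_parameter_count(block: EncoderBlock) -> int:
    return block.mixer.n_parameters()


def deploy_model(model) -> "Module":
    """Convert a trained classifier to its single-path inference topology.

    Requires the model to be in inference mode (frozen normalization
    statistics); every multi-branch mixer is replaced by its fused
    equivalent and everything else is shared structure copied as-is.
    """
    if model.training:
        raise RuntimeError(
            "deploy requires inference mode (call .eval() first): batch-norm "
            "statistics must be frozen before fusion"
        )
    if getattr(model, "topology", TOPOLOGY_MULTI_BRANCH) == TOPOLOGY_FUSED:
        raise RuntimeError("model is already fused")
    deployed = copy.deepcopy(model)
    for i, block in enumerate(model.encoder.blocks):
        fused = fuse_block(block)
        deployed.encoder._modules[f"block{i}"] = fused
        deployed.encoder.blocks[i] = fused
        setattr(deployed.encoder, f"block{i}", fused)
    deployed.topology = TOPOLOGY_FUSED
    deployed.train(False)
    return deployed
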