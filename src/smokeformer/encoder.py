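"""Improved Poolformer encoder: MetaFormer blocks with a convolutional mixer.

Each of the L blocks follows the MetaFormer template — a token mixer and a
channel MLP, each on a residual path.  Here the mixer is a ConvNeXt-like
multi-branch structure on the token grid: parallel depthwise convolutions
(default 7x7 and 3x3), each followed by its own batch normalization, plus an
identity branch.  The identity branch doubles as the mixer's residual path,
which is what lets the whole multi-branch structure later collapse into a
single depthwise convolution (see :mod:`smokeformer.reparam`).

Token mixing works on the spatial grid, so the sequence is mapped to a
channel-first feature map (the dimension interchange between token/height and
channel axes), mixed, and mapped back.  A class token, if present, bypasses
the mixer and rejoins the sequence for the channel MLP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import (GELU, BatchNorm2d, DepthwiseConv2d, LayerNorm, Linear,
                     Module, Sequential)
from .tokenizer import TokenSequence

__all__ = [
    "EncoderConfig",
    "MultiBranchMixer",
    "EncoderBlock",
    "Encoder",
    "seq_to_grid",
    "grid_to_seq",
]


@dataclass
class EncoderConfig:
    """Encoder hyperparameters.

    depth
        Number of stacked blocks (L).  The reference training setup uses 10.
    branch_kernel_sizes
        Depthwise kernel sizes of the mixer branches, largest first; all odd.
    include_identity_branch
        Adds the identity path to the mixer (and with it the mixer residual).
    """

    depth: int = 10
    embed_dim: int = 64
    mlp_ratio: int = 4
    branch_kernel_sizes: tuple[int, ...] = (7, 3)
    include_identity_branch: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.branch_kernel_sizes:
            raise ValueError("at least one branch kernel required")
        if any(k % 2 == 0 for k in self.branch_kernel_sizes):
            raise ValueError("branch kernels must be odd")
        if max(self.branch_kernel_sizes) != self.branch_kernel_sizes[0]:
            raise ValueError("list the largest branch kernel first")

    def validate_grid(self, grid: tuple[int, int]) -> None:
        k = max(self.branch_kernel_sizes)
        if k > grid[0] * 2 - 1 or k > grid[1] * 2 - 1:
            raise ValueError(f"branch kernel {k} too large for token grid {grid}")


def seq_to_grid(seq: TokenSequence) -> tuple[np.ndarray, np.ndarray | None]:
    """Token sequence -> channel-first feature map (B, C, Hg, Wg).

    The class token (if any) is detached and returned alongside.  Inverse of
    :func:`grid_to_seq`.
    """
    if seq.grid is None:
        raise ValueError("token sequence has no grid metadata")
    hg, wg = seq.grid
    tokens = seq.tokens
    cls = None
    if seq.class_token:
        cls = tokens[:, 0, :]
        tokens = tokens[:, 1:, :]
    b, n, c = tokens.shape
    fmap = np.ascontiguousarray(tokens.reshape(b, hg, wg, c).transpose(0, 3, 1, 2))
    return fmap, cls


def grid_to_seq(fmap: np.ndarray, cls: np.ndarray | None = None) -> TokenSequence:
    """Feature map (B, C, Hg, Wg) -> token sequence; re-attaches ``cls``."""
    b, c, hg, wg = fmap.shape
    tokens = fmap.transpose(0, 2, 3, 1).reshape(b, hg * wg, c)
    if cls is not None:
        tokens = np.concatenate([cls[:, None, :], tokens], axis=1)
    return TokenSequence(tokens=np.ascontiguousarray(tokens), grid=(hg, wg),
                         class_token=cls is not None)


class MultiBranchMixer(Module):
    """Sum of parallel (depthwise conv -> batch norm) branches + identity.

    The identity branch carries no normalization; it is the residual path of
    the mixer and fuses to a centred Dirac kernel.
    """

    def __init__(self, channels: int, kernel_sizes: tuple[int, ...] = (7, 3),
                 include_identity: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.channels = channels
        self.kernel_sizes = tuple(kernel_sizes)
        self.include_identity = include_identity
        self.branches: list[Sequential] = []
        for i, k in enumerate(self.kernel_sizes):
            branch = Sequential(
                DepthwiseConv2d(channels, k, bias=False, rng=rng),
                BatchNorm2d(channels),
            )
            self.add_module(f"branch{i}", branch)
            self.branches.append(branch)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = x.copy() if self.include_identity else np.zeros_like(x)
        for branch in self.branches:
            out += branch(x)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = grad.copy() if self.include_identity else np.zeros_like(grad)
        for branch in self.branches:
            dx += branch.backward(grad)
        return dx


class EncoderBlock(Module):
    """One MetaFormer block: token mixer then channel MLP, each residual.

    The mixer residual is the mixer's identity branch (so the fused inference
    block stays single-path); with the identity branch disabled an explicit
    residual addition is used instead.  The MLP half is the standard
    pre-norm residual: ``z = y + W2 GELU(W1 LN(y))``.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        c = cfg.embed_dim
        self.cfg = cfg
        self.add_module("mixer", MultiBranchMixer(
            c, cfg.branch_kernel_sizes, cfg.include_identity_branch, rng=rng))
        self.add_module("norm", LayerNorm(c))
        self.add_module("fc1", Linear(c, cfg.mlp_ratio * c, rng=rng))
        self.add_module("act", GELU())
        self.add_module("fc2", Linear(cfg.mlp_ratio * c, c, rng=rng))

    # mixer half -----------------------------------------------------------
    def _mix(self, seq: TokenSequence) -> TokenSequence:
        fmap, cls = seq_to_grid(seq)
        mixed = self.mixer(fmap)
        if not self.cfg.include_identity_branch:
            mixed = mixed + fmap
        self._had_cls = cls is not None
        return grid_to_seq(mixed, cls)

    def _mix_backward(self, grad_tokens: np.ndarray) -> np.ndarray:
        gcls = None
        if self._had_cls:
            gcls = grad_tokens[:, 0, :]
            grad_tokens = grad_tokens[:, 1:, :]
        b, n, c = grad_tokens.shape
        hg, wg = self._grid
        gmap = np.ascontiguousarray(grad_tokens.reshape(b, hg, wg, c).transpose(0, 3, 1, 2))
        dmap = self.mixer.backward(gmap)
        if not self.cfg.include_identity_branch:
            dmap = dmap + gmap
        dtokens = dmap.transpose(0, 2, 3, 1).reshape(b, n, c)
        if gcls is not None:
            dtokens = np.concatenate([gcls[:, None, :], dtokens], axis=1)
        return np.ascontiguousarray(dtokens)

    # full block -------------------------------------------------------------
    def forward(self, seq: TokenSequence) -> TokenSequence:
        self.cfg.validate_grid(seq.grid)
        self._grid = seq.grid
        y = self._mix(seq)
        self._y_tokens = y.tokens
        mlp = self.fc2(self.act(self.fc1(self.norm(y.tokens))))
        return TokenSequence(tokens=y.tokens + mlp, grid=y.grid,
                             class_token=y.class_token)

    def backward(self, grad_tokens: np.ndarray) -> np.ndarray:
        dmlp = self.norm.backward(
            self.fc1.backward(self.act.backward(self.fc2.backward(grad_tokens)))
        )
        dy = grad_tokens + dmlp
        return self._mix_backward(dy)


class Encoder(Module):
    """Stack of L encoder blocks at a single token-grid resolution."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.cfg = cfg
        self.blocks: list[EncoderBlock] = []
        for i in range(cfg.depth):
            block = EncoderBlock(cfg, rng=rng)
            self.add_module(f"block{i}", block)
            self.blocks.append(block)

    def forward(self, seq: TokenSequence) -> TokenSequence:
        for block in self.blocks:
            seq = block(seq)
        return seq

    def backward(self, grad_tokens: np.ndarray) -> np.ndarray:
        for block in reversed(self.blocks):
            grad_tokens = block.backward(grad_tokens)
        return grad_tokens
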