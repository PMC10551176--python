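"""Convolutional tokenization: image -> positional-embedded token sequence.

Instead of ViT's large-stride patch projection, the stem extracts features
with small-kernel convolutions, GELU activations, max pooling and one
residual block, then flattens the final feature map into tokens.  The token
count is a pure function of the input size and the configured strides, so the
same stem handles any input meeting the minimum size.

Convolutions in the stem use replicate (edge) padding so that a spatially
constant image produces identical tokens on the whole grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import GELU, Conv2d, MaxPool2d, Module, Sequential

__all__ = [
    "TokenizerConfig",
    "TokenSequence",
    "Tokenizer",
    "ResidualBlock",
    "PositionalEmbedding",
]


@dataclass
class TokenizerConfig:
    """Stem layout.

    The stem is: conv3x3 stride 2 (3 -> stem_channels[0]) -> GELU ->
    maxpool 3x3 stride 2 -> residual block -> one conv3x3 stride 2 per
    remaining width in ``stem_channels[1:] + (embed_dim,)`` (GELU between
    them).  Total stride is ``4 * 2**len(stem_channels)``.
    """

    embed_dim: int = 64
    stem_channels: tuple[int, ...] = (32,)
    kernel_size: int = 3
    pool_size: int = 3
    pool_stride: int = 2
    include_residual_block: bool = True
    class_token: bool = False

    def __post_init__(self) -> None:
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        if not self.stem_channels:
            raise ValueError("stem_channels must list at least one width")

    @property
    def total_stride(self) -> int:
        return 2 * self.pool_stride * 2 ** len(self.stem_channels)

    @classmethod
    def small(cls, embed_dim: int = 64, class_token: bool = False) -> "TokenizerConfig":
        """Stride-8 stem for small inputs."""
        return cls(embed_dim=embed_dim, stem_channels=(max(embed_dim // 2, 8),),
                   class_token=class_token)

    @classmethod
    def vit_b16_compatible(cls) -> "TokenizerConfig":
        """Stride-16 / 768-channel stem; with the class token a 224x224
        input yields a 197x768 sequence."""
        return cls(embed_dim=768, stem_channels=(64, 256), class_token=True)


@dataclass
class TokenSequence:
    """N tokens x C channels with the spatial grid they came from.

    If ``class_token`` is set, token 0 is the class token and the grid tokens
    follow; otherwise all N tokens lie on the grid.
    """

    tokens: np.ndarray  # (B, N, C)
    grid: tuple[int, int]
    class_token: bool = False

    def __post_init__(self) -> None:
        n = self.tokens.shape[-2]
        expect = self.grid[0] * self.grid[1] + (1 if self.class_token else 0)
        if n < 1 or n != expect:
            raise ValueError(
                f"token count {n} inconsistent with grid {self.grid} "
                f"(class_token={self.class_token})"
            )

    @property
    def embed_dim(self) -> int:
        return self.tokens.shape[-1]

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[-2]


class ResidualBlock(Module):
    """conv -> GELU -> conv plus shortcut; 1x1 projection when widths differ.

    With all branch weights and biases zero the block is the identity map.
    """

    def __init__(self, in_channels: int, out_channels: int | None = None, *,
                 kernel_size: int = 3, pad_mode: str = "edge",
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        out_channels = out_channels or in_channels
        p = kernel_size // 2
        self.add_module("conv1", Conv2d(in_channels, out_channels, kernel_size,
                                        padding=p, pad_mode=pad_mode, rng=rng))
        self.add_module("act", GELU())
        self.add_module("conv2", Conv2d(out_channels, out_channels, kernel_size,
                                        padding=p, pad_mode=pad_mode, rng=rng))
        self.projected = in_channels != out_channels
        if self.projected:
            self.add_module("proj", Conv2d(in_channels, out_channels, 1, rng=rng))

    def forward(self, x: np.ndarray) -> np.ndarray:
        branch = self.conv2(self.act(self.conv1(x)))
        shortcut = self.proj(x) if self.projected else x
        return shortcut + branch

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dbranch = self.conv1.backward(self.act.backward(self.conv2.backward(grad)))
        dshort = self.proj.backward(grad) if self.projected else grad
        return dbranch + dshort


class Tokenizer(Module):
    """The convolutional stem; flattens its output grid into tokens."""

    def __init__(self, cfg: TokenizerConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        k = cfg.kernel_size
        p = k // 2
        layers: list[Module] = [
            Conv2d(3, cfg.stem_channels[0], k, stride=2, padding=p,
                   pad_mode="edge", rng=rng),
            GELU(),
            MaxPool2d(cfg.pool_size, cfg.pool_stride, cfg.pool_size // 2, pad_mode="edge"),
        ]
        if cfg.include_residual_block:
            layers.append(ResidualBlock(cfg.stem_channels[0], rng=rng))
        widths = list(cfg.stem_channels[1:]) + [cfg.embed_dim]
        c_in = cfg.stem_channels[0]
        for i, c_out in enumerate(widths):
            if i > 0:
                layers.append(GELU())
            layers.append(Conv2d(c_in, c_out, k, stride=2, padding=p,
                                 pad_mode="edge", rng=rng))
            c_in = c_out
        self.add_module("stem", Sequential(*layers))
        if cfg.class_token:
            self.add_param("cls", np.zeros(cfg.embed_dim))

    def forward(self, images: np.ndarray) -> TokenSequence:
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError("expected images of shape (B, 3, H, W)")
        stride = self.cfg.total_stride
        if images.shape[2] < stride or images.shape[3] < stride:
            raise ValueError(
                f"input {images.shape[2]}x{images.shape[3]} below the minimum "
                f"{stride}x{stride} required by total stride {stride}"
            )
        fmap = self.stem(images)  # (B, C, Hg, Wg)
        b, c, hg, wg = fmap.shape
        tokens = fmap.transpose(0, 2, 3, 1).reshape(b, hg * wg, c)
        if self.cfg.class_token:
            cls = np.broadcast_to(self.cls, (b, 1, c))
            tokens = np.concatenate([cls, tokens], axis=1)
        self._grid = (hg, wg)
        return TokenSequence(tokens=tokens, grid=(hg, wg),
                             class_token=self.cfg.class_token)

    def backward(self, grad_tokens: np.ndarray) -> np.ndarray:
        hg, wg = self._grid
        if self.cfg.class_token:
            self._grads["cls"] += grad_tokens[:, 0, :].sum(axis=0)
            grad_tokens = grad_tokens[:, 1:, :]
        b = grad_tokens.shape[0]
        gmap = grad_tokens.reshape(b, hg, wg, -1).transpose(0, 3, 1, 2)
        return self.stem.backward(np.ascontiguousarray(gmap))


class PositionalEmbedding(Module):
    """Learnable, zero-initialized N x C table added to the token sequence."""

    def __init__(self, n_tokens: int, embed_dim: int) -> None:
        super().__init__()
        self.add_param("table", np.zeros((n_tokens, embed_dim)))

    def forward(self, seq: TokenSequence) -> TokenSequence:
        if seq.tokens.shape[1:] != self.table.shape:
            raise ValueError(
                f"embedding table {self.table.shape} does not match token "
                f"sequence {seq.tokens.shape[1:]}"
            )
        return TokenSequence(tokens=seq.tokens + self.table, grid=seq.grid,
                             class_token=seq.class_token)

    def backward(self, grad_tokens: np.ndarray) -> np.ndarray:
        self._grads["table"] += grad_tokens.sum(axis=0)
        return grad_tokens
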