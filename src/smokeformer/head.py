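"""Sequence pooling, linear classification, and full model assembly.

Instead of slicing off a class token, the encoder output is reduced by
sequence pooling: a learned scalar score per token, softmax-normalized over
the sequence, weights an average of the tokens.  The pooled feature goes
through a linear classifier (optionally one hidden layer) to two logits,
smoke vs smoke-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import Encoder, EncoderConfig
from .layers import GELU, Linear, Module, softmax
from .tokenizer import PositionalEmbedding, Tokenizer, TokenizerConfig, TokenSequence

__all__ = [
    "Prediction",
    "ModelConfig",
    "SequencePool",
    "SmokeClassifier",
    "CLASS_NAMES",
]

CLASS_NAMES = ("smoke_free", "smoke")  # index 1 (smoke) is the positive class


@dataclass
class Prediction:
    """Classifier output for one image."""

    logits: np.ndarray      # (2,)
    label: str              # argmax class name
    score: float            # softmax probability of the predicted class

    @classmethod
    def from_logits(cls, logits: np.ndarray) -> "Prediction":
        probs = softmax(logits.astype(np.float64))
        idx = int(np.argmax(logits))
        return cls(logits=logits, label=CLASS_NAMES[idx], score=float(probs[idx]))


@dataclass
class ModelConfig:
    """Full classifier configuration."""

    input_size: int = 64
    embed_dim: int = 64
    depth: int = 10
    mlp_ratio: int = 4
    branch_kernel_sizes: tuple[int, ...] = (7, 3)
    include_identity_branch: bool = True
    class_token: bool = False
    hidden_head: int = 0  # 0 = single linear layer; >0 = one hidden layer
    n_classes: int = 2
    seed: int = 0

    def tokenizer_config(self) -> TokenizerConfig:
        return TokenizerConfig.small(embed_dim=self.embed_dim,
                                     class_token=self.class_token)

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(depth=self.depth, embed_dim=self.embed_dim,
                             mlp_ratio=self.mlp_ratio,
                             branch_kernel_sizes=self.branch_kernel_sizes,
                             include_identity_branch=self.include_identity_branch)

    def to_dict(self) -> dict:
        import dataclasses
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "branch_kernel_sizes" in d:
            d["branch_kernel_sizes"] = tuple(d["branch_kernel_sizes"])
        return cls(**d)


class SequencePool(Module):
    """Attention-weighted token average with a learned scalar scorer."""

    def __init__(self, embed_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.add_module("scorer", Linear(embed_dim, 1, rng=rng))

    def forward(self, tokens: np.ndarray) -> np.ndarray:
        if tokens.ndim != 3 or tokens.shape[1] < 1:
            raise ValueError("expected a non-empty (B, N, C) token array")
        scores = self.scorer(tokens)[..., 0]          # (B, N)
        attn = softmax(scores, axis=-1)               # rows sum to 1
        self._tokens, self._attn = tokens, attn
        return np.einsum("bn,bnc->bc", attn, tokens)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        tokens, attn = self._tokens, self._attn
        dtokens = attn[..., None] * grad[:, None, :]
        dattn = np.einsum("bnc,bc->bn", tokens, grad)
        dscores = attn * (dattn - (attn * dattn).sum(axis=-1, keepdims=True))
        dtokens += self.scorer.backward(dscores[..., None])
        return dtokens

    def attention(self, tokens: np.ndarray) -> np.ndarray:
        """Attention weights only (each row sums to 1)."""
        return softmax(self.scorer(tokens)[..., 0], axis=-1)


class SmokeClassifier(Module):
    """Tokenizer -> positional embedding -> encoder -> sequence pool -> logits."""

    def __init__(self, cfg: ModelConfig) -> None:
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.topology = "multi_branch"
        tok_cfg = cfg.tokenizer_config()
        self.add_module("tokenizer", Tokenizer(tok_cfg, rng=rng))
        stride = tok_cfg.total_stride
        if cfg.input_size % stride:
            raise ValueError(
                f"input_size {cfg.input_size} not divisible by stem stride {stride}"
            )
        grid = cfg.input_size // stride
        n_tokens = grid * grid + (1 if cfg.class_token else 0)
        self.add_module("pos_embed", PositionalEmbedding(n_tokens, cfg.embed_dim))
        self.add_module("encoder", Encoder(cfg.encoder_config(), rng=rng))
        self.add_module("pool", SequencePool(cfg.embed_dim, rng=rng))
        if cfg.hidden_head:
            self.add_module("head", Linear(cfg.embed_dim, cfg.hidden_head, rng=rng))
            self.add_module("head_act", GELU())
            self.add_module("head_out", Linear(cfg.hidden_head, cfg.n_classes, rng=rng))
        else:
            self.add_module("head_out", Linear(cfg.embed_dim, cfg.n_classes, rng=rng))

    # ------------------------------------------------------------------
    def forward(self, images: np.ndarray) -> np.ndarray:
        """Images (B, 3, H, W) in [0, 1] -> logits (B, n_classes)."""
        seq = self.pos_embed(self.tokenizer(images))
        seq = self.encoder(seq)
        feat = self.pool(seq.tokens)
        if self.cfg.hidden_head:
            feat = self.head_act(self.head(feat))
        return self.head_out(feat)

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = self.head_out.backward(grad_logits)
        if self.cfg.hidden_head:
            g = self.head.backward(self.head_act.backward(g))
        g = self.pool.backward(g)
        g = self.encoder.backward(g)
        g = self.pos_embed.backward(g)
        return self.tokenizer.backward(g)

    # ------------------------------------------------------------------
    def predict(self, images: np.ndarray) -> list[Prediction]:
        logits = self.forward(images)
        return [Prediction.from_logits(row) for row in logits]

    def predict_labels(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class indices for a (possibly large) image array, batched."""
        out = []
        for start in range(0, images.shape[0], batch_size):
            logits = self.forward(images[start:start + batch_size])
            out.append(np.argmax(logits, axis=-1))
        return np.concatenate(out) if out else np.zeros(0, dtype=int)
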