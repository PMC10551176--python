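"""Minimal NumPy neural-network layers with explicit backpropagation.

Everything the classifier needs — dense and convolutional layers, batch/layer
normalization, exact GELU, max pooling — implemented on float32 ``numpy``
arrays in NCHW / (B, N, C) layout.  Each :class:`Module` caches what its
backward pass needs during ``forward`` and accumulates parameter gradients in
place; the whole stack is trained with :class:`AdamW`.

Gradients are verified against central finite differences in the test suite,
which is the correctness contract for this file.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

__all__ = [
    "Module",
    "Sequential",
    "Linear",
    "Conv2d",
    "DepthwiseConv2d",
    "MaxPool2d",
    "BatchNorm2d",
    "LayerNorm",
    "GELU",
    "AdamW",
    "gelu",
    "gelu_grad",
]

_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    """Exact GELU, ``x * Phi(x)`` with Phi the standard normal CDF."""
    return x * ndtr(x)


def gelu_grad(x: np.ndarray) -> np.ndarray:
    """d/dx of exact GELU: ``Phi(x) + x * phi(x)``."""
    return ndtr(x) + x * _INV_SQRT_2PI * np.exp(-0.5 * x * x)


class Module:
    """Base class: parameter/buffer registry plus train/eval mode.

    Parameters are float32 arrays updated in place by the optimizer; buffers
    (e.g. batch-norm running statistics) are saved with the parameters but
    receive no gradient.
    """

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    # -- registration -----------------------------------------------------
    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.ascontiguousarray(value, dtype=np.float32)
        self._params[name] = arr
        self._grads[name] = np.zeros_like(arr)
        setattr(self, name, arr)
        return arr

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.ascontiguousarray(value, dtype=np.float32)
        self._buffers[name] = arr
        setattr(self, name, arr)
        return arr

    def add_module(self, name: str, module: "Module") -> "Module":
        self._modules[name] = module
        setattr(self, name, module)
        return module

    # -- traversal --------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_parameters(prefix + name + "."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._grads.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_grads(prefix + name + "."))
        return out

    def named_buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._buffers.items()}
        for name, mod in self._modules.items():
            out.update(mod.named_buffers(prefix + name + "."))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        d = self.named_parameters()
        d.update(self.named_buffers())
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)}")
        for name, arr in own.items():
            src = np.asarray(state[name], dtype=np.float32)
            if src.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {src.shape} vs {arr.shape}"
                )
            arr[...] = src

    def zero_grad(self) -> None:
        for g in self._grads.values():
            g[...] = 0.0
        for mod in self._modules.values():
            mod.zero_grad()

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.named_parameters().values())

    # -- interface --------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.layers = list(modules)
        for i, m in enumerate(modules):
            self.add_module(str(i), m)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.layers:
            x = m(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(self.layers):
            grad = m.backward(grad)
        return grad


class Linear(Module):
    """Affine map on the last axis: ``y = x @ W.T + b``."""

    def __init__(self, in_features: int, out_features: int, *, bias: bool = True,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.add_param("weight", rng.normal(0.0, scale, (out_features, in_features)))
        self.has_bias = bias
        if bias:
            self.add_param("bias", np.zeros(out_features))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.weight.T
        if self.has_bias:
            y = y + self.bias
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gflat = grad.reshape(-1, grad.shape[-1])
        xflat = self._x.reshape(-1, self._x.shape[-1])
        self._grads["weight"] += gflat.T @ xflat
        if self.has_bias:
            self._grads["bias"] += gflat.sum(axis=0)
        return grad @ self.weight


class GELU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return gelu(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * gelu_grad(self._x)


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Padded NCHW input -> (B, Ho, Wo, C*k*k) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B, C, Ho, Wo, k, k)
    b, c, ho, wo = win.shape[:4]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho, wo, c * k * k)


def _unpad_grad(dxp: np.ndarray, p: int, mode: str) -> np.ndarray:
    """Fold the gradient of a padded array back onto the unpadded input."""
    if p == 0:
        return dxp
    if mode == "constant":
        return dxp[:, :, p:-p, p:-p]
    # edge padding: pad strips were copies of the border rows/cols
    d = dxp.copy()
    d[:, :, p, :] += d[:, :, :p, :].sum(axis=2)
    d[:, :, -p - 1, :] += d[:, :, -p:, :].sum(axis=2)
    d = d[:, :, p:-p, :]
    d[:, :, :, p] += d[:, :, :, :p].sum(axis=3)
    d[:, :, :, -p - 1] += d[:, :, :, -p:].sum(axis=3)
    return d[:, :, :, p:-p]


def _col2im(dcols: np.ndarray, xp_shape: tuple[int, ...], k: int, stride: int) -> np.ndarray:
    """Scatter-add patch gradients back to the padded input."""
    b, ho, wo, _ = dcols.shape
    c = xp_shape[1]
    d = dcols.reshape(b, ho, wo, c, k, k)
    dxp = np.zeros(xp_shape, dtype=dcols.dtype)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += (
                d[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            )
    return dxp


class Conv2d(Module):
    """Standard cross-channel 2-D convolution (im2col implementation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, *,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 pad_mode: str = "constant",
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if pad_mode not in ("constant", "edge"):
            raise ValueError(f"unknown pad_mode {pad_mode!r}")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size * kernel_size
        self.add_param(
            "weight",
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, kernel_size, kernel_size)),
        )
        self.has_bias = bias
        if bias:
            self.add_param("bias", np.zeros(out_channels))
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if x.shape[2] + 2 * p < k or x.shape[3] + 2 * p < k:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than kernel {k} after padding"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode=self.pad_mode) if p else x
        cols = _im2col(xp, k, s)
        self._cols, self._xp_shape = cols, xp.shape
        co = self.weight.shape[0]
        y = cols @ self.weight.reshape(co, -1).T
        if self.has_bias:
            y = y + self.bias
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        co = self.weight.shape[0]
        gb = grad.transpose(0, 2, 3, 1)  # (B, Ho, Wo, Co)
        gflat = gb.reshape(-1, co)
        self._grads["weight"] += (
            gflat.T @ self._cols.reshape(-1, self._cols.shape[-1])
        ).reshape(self.weight.shape)
        if self.has_bias:
            self._grads["bias"] += gflat.sum(axis=0)
        dcols = gb @ self.weight.reshape(co, -1)
        dxp = _col2im(dcols, self._xp_shape, k, s)
        return _unpad_grad(dxp, p, self.pad_mode)


class DepthwiseConv2d(Module):
    """Depthwise conv, stride 1, "same" padding: one k x k kernel per channel."""

    def __init__(self, channels: int, kernel_size: int, *, bias: bool = False,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = kernel_size * kernel_size
        self.add_param(
            "weight",
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (channels, kernel_size, kernel_size)),
        )
        self.has_bias = bias
        if bias:
            self.add_param("bias", np.zeros(channels))
        self.channels = channels
        self.kernel_size = kernel_size

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        p = k // 2
        h, w = x.shape[2], x.shape[3]
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp, self._hw = xp, (h, w)
        y = np.zeros_like(x)
        for ki in range(k):
            for kj in range(k):
                y += self.weight[:, ki, kj][None, :, None, None] * xp[:, :, ki:ki + h, kj:kj + w]
        if self.has_bias:
            y += self.bias[None, :, None, None]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        h, w = self._hw
        dxp = np.zeros_like(self._xp)
        dw = self._grads["weight"]
        for ki in range(k):
            for kj in range(k):
                patch = self._xp[:, :, ki:ki + h, kj:kj + w]
                dw[:, ki, kj] += np.einsum("bchw,bchw->c", grad, patch)
                dxp[:, :, ki:ki + h, kj:kj + w] += grad * self.weight[:, ki, kj][None, :, None, None]
        if self.has_bias:
            self._grads["bias"] += grad.sum(axis=(0, 2, 3))
        p = k // 2
        return dxp[:, :, p:-p, p:-p] if p else dxp


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0,
                 pad_mode: str = "constant") -> None:
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        self.pad_mode = pad_mode

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            if self.pad_mode == "constant":
                xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
            else:
                xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")
        else:
            xp = x
        b, c, hp, wp = xp.shape
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        self._argmax = flat.argmax(axis=-1)
        self._xp_shape = xp.shape
        return np.ascontiguousarray(flat.max(axis=-1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        b, c, ho, wo = grad.shape
        dflat = np.zeros((b, c, ho, wo, k * k), dtype=grad.dtype)
        np.put_along_axis(dflat, self._argmax[..., None], grad[..., None], axis=-1)
        # reuse col2im scatter: reorder to (B, Ho, Wo, C*k*k)
        dcols = dflat.reshape(b, c, ho, wo, k, k).transpose(0, 2, 3, 1, 4, 5).reshape(
            b, ho, wo, c * k * k
        )
        dxp = _col2im(dcols, self._xp_shape, k, s)
        return _unpad_grad(dxp, p, self.pad_mode)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.add_param("gamma", np.ones(channels))
        self.add_param("beta", np.zeros(channels))
        self.add_buffer("running_mean", np.zeros(channels))
        self.add_buffer("running_var", np.ones(channels))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv = xhat, inv
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self._grads["gamma"] += np.einsum("bchw,bchw->c", grad, xhat)
        self._grads["beta"] += grad.sum(axis=(0, 2, 3))
        ghat = grad * self.gamma[None, :, None, None]
        if not self.training:
            return ghat * inv[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        mean_g = ghat.sum(axis=(0, 2, 3)) / m
        mean_gx = np.einsum("bchw,bchw->c", ghat, xhat) / m
        return inv[None, :, None, None] * (
            ghat - mean_g[None, :, None, None] - xhat * mean_gx[None, :, None, None]
        )


class LayerNorm(Module):
    """Normalization over the trailing (channel) axis of (..., C) arrays."""

    def __init__(self, channels: int, eps: float = 1e-6) -> None:
        super().__init__()
        self.add_param("gamma", np.ones(channels))
        self.add_param("beta", np.zeros(channels))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat, self._inv = (x - mean) * inv, inv
        return self.gamma * self._xhat + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        gflat = grad.reshape(-1, grad.shape[-1])
        self._grads["gamma"] += np.einsum("nc,nc->c", gflat, xhat.reshape(-1, xhat.shape[-1]))
        self._grads["beta"] += gflat.sum(axis=0)
        ghat = grad * self.gamma
        mean_g = ghat.mean(axis=-1, keepdims=True)
        mean_gx = (ghat * xhat).mean(axis=-1, keepdims=True)
        return inv * (ghat - mean_g - xhat * mean_gx)


class AdamW:
    """AdamW with decoupled weight decay applied to >=2-D parameters only."""

    def __init__(self, model: Module, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4) -> None:
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        params = model.named_parameters()
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        params = self.model.named_parameters()
        grads = self.model.named_grads()
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, p in params.items():
            g = grads[name]
            m, v = self._m[name], self._v[name]
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and p.ndim >= 2:
                update = update + self.weight_decay * p
            p -= self.lr * update


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    probs = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(np.float32)
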