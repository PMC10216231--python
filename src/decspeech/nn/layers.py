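"""Minimal dense/convolutional layer library with explicit backprop.

NCHW tensors; parameters are float32 by default (float64 available via
the ``dtype`` argument for finite-difference gradient checking).  Each layer caches what its backward
pass needs during forward; ``Sequential`` chains layers and exposes a
flat ``state_dict`` (trainable parameters and running buffers) so
optimizer steps and exponential-moving-average teacher updates can
operate on plain arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: parameter/gradient/buffer dicts plus forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv2d(Layer):
    """3x3 convolution (stride 1) via im2col; 'same' or 'valid' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 padding: str = "same", rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        rng = rng or np.random.default_rng(0)
        self.k = kernel
        self.pad = (kernel - 1) // 2 if padding == "same" else 0
        self.dtype = dtype
        fan_in = in_channels * kernel * kernel
        bound = np.sqrt(6.0 / fan_in)  # He-uniform
        self.params["weight"] = rng.uniform(
            -bound, bound, (out_channels, in_channels, kernel, kernel)).astype(dtype)
        self.params["bias"] = np.zeros(out_channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train):
        x = np.asarray(x, dtype=self.dtype)
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = x.shape
        ho, wo = hp - k + 1, wp - k + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))         # (n,c,ho,wo,k,k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        w = self.params["weight"].reshape(self.params["weight"].shape[0], -1)
        out = col @ w.T + self.params["bias"]
        self._cache = (col, (n, c, hp, wp, ho, wo))
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        dout = np.asarray(dout, dtype=self.dtype)
        col, (n, c, hp, wp, ho, wo) = self._cache
        k, p = self.k, self.pad
        oc = dout.shape[1]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, oc)
        self.grads["weight"] += (dflat.T @ col).reshape(self.params["weight"].shape)
        self.grads["bias"] += dflat.sum(axis=0)
        w = self.params["weight"].reshape(oc, -1)
        dcol = (dflat @ w).reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, hp, wp), dtype=self.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + ho, kj:kj + wo] += dcol[:, :, :, :, ki, kj]
        return dxp[:, :, p:hp - p, p:wp - p] if p else dxp


class BatchNorm(Layer):
    """Batch normalization over (N,) or (N, H, W) per channel.

    Running statistics (momentum 0.9) are buffers, used in eval mode.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.9,
                 dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.dtype = dtype
        self.params["gamma"] = np.ones(num_features, dtype=dtype)
        self.params["beta"] = np.zeros(num_features, dtype=dtype)
        self.buffers["running_mean"] = np.zeros(num_features, dtype=dtype)
        self.buffers["running_var"] = np.ones(num_features, dtype=dtype)
        self.zero_grad()

    def _axes_shape(self, x):
        if x.ndim == 2:
            return (0,), (1, -1)
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        raise ValueError(f"BatchNorm expects 2-D or 4-D input, got {x.ndim}-D")

    def forward(self, x, train):
        x = np.asarray(x, dtype=self.dtype)
        axes, bshape = self._axes_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.buffers["running_mean"] = (self.momentum * self.buffers["running_mean"]
                                            + (1 - self.momentum) * mean)
            self.buffers["running_var"] = (self.momentum * self.buffers["running_var"]
                                           + (1 - self.momentum) * var)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        std = np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(bshape)) / std.reshape(bshape)
        self._cache = (xhat, std, axes, bshape, train)
        return self.params["gamma"].reshape(bshape) * xhat + self.params["beta"].reshape(bshape)

    def backward(self, dout):
        xhat, std, axes, bshape, train = self._cache
        dout = np.asarray(dout, dtype=self.dtype)
        g = self.params["gamma"].reshape(bshape)
        self.grads["gamma"] += (dout * xhat).sum(axis=axes)
        self.grads["beta"] += dout.sum(axis=axes)
        if not train:
            return dout * g / std.reshape(bshape)
        m = dout.size // dout.shape[1] if dout.ndim == 4 else dout.shape[0]
        dxhat = dout * g
        term = dxhat - dxhat.mean(axis=axes).reshape(bshape) \
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(bshape)
        return term / std.reshape(bshape)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        neg = self.alpha * (np.exp(np.minimum(x, 0)) - 1.0)
        self._cache = (x > 0, neg)
        return np.where(x > 0, x, neg)

    def backward(self, dout):
        pos, neg = self._cache
        return dout * np.where(pos, 1.0, neg + self.alpha)


class Sigmoid(Layer):
    def forward(self, x, train):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5) \
              .reshape(n, c, h // 2, w // 2, 4)
        self._idx = np.argmax(xr, axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        return dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
                    .reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""

    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.dtype = dtype
        bound = np.sqrt(6.0 / (in_features + out_features))  # Xavier-uniform
        self.params["weight"] = rng.uniform(
            -bound, bound, (in_features, out_features)).astype(dtype)
        self.params["bias"] = np.zeros(out_features, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train):
        x = np.asarray(x, dtype=self.dtype)
        self._x = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, dout):
        dout = np.asarray(dout, dtype=self.dtype)
        self.grads["weight"] += self._x.T @ dout
        self.grads["bias"] += dout.sum(axis=0)
        return dout @ self.params["weight"].T


class Dropout(Layer):
    """Inverted dropout with drop probability p; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("drop probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.dtype)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self):
        """Yield (layer, name) pairs for every trainable array."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.named_params()
            else:
                for name in layer.params:
                    yield layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                for k, v in layer.state_dict().items():
                    state[f"{i}.{k}"] = v
            else:
                for k, v in layer.params.items():
                    state[f"{i}.{k}"] = v
                for k, v in layer.buffers.items():
                    state[f"{i}.buf.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)[:5]}")
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                layer.load_state_dict({k[len(f"{i}."):]: v for k, v in state.items()
                                       if k.startswith(f"{i}.")})
            else:
                for k in layer.params:
                    layer.params[k] = state[f"{i}.{k}"].astype(layer.params[k].dtype)
                for k in layer.buffers:
                    layer.buffers[k] = state[f"{i}.buf.{k}"].astype(layer.buffers[k].dtype)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
            elif isinstance(layer, Sequential):
                layer.set_dropout_rng(rng)
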