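"""Compact CPU neural-network machinery for the epoch classifiers.

Implements exactly the pieces the discharge classifiers need — temporal
convolution, batch normalization, ReLU, max pooling, a dense softmax head,
categorical cross-entropy, and RMSprop — as plain numpy with explicit
forward/backward passes.  Convolutions are realized as strided window views
followed by BLAS matrix products, which keeps small-batch training on a
single CPU core fast enough for the scaled experiments in this package.

All randomness flows through explicitly passed generators, so training is
bit-reproducible for fixed seeds.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def conv_output_len(length: int, kernel: int, stride: int) -> int:
    """Closed-form output length of a valid convolution/pool: floor((L-k)/s)+1."""
    return (length - kernel) // stride + 1


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[dict]:
        return []

    def state(self) -> dict:
        return {f"p{i}": p["value"].copy() for i, p in enumerate(self.parameters())}

    def load_state(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p["value"][...] = state[f"p{i}"]


class Conv1d(Layer):
    """Temporal convolution over (batch, channels, length), stride 1.

    ``padding='same'`` zero-pads so the output length equals the input length;
    ``'valid'`` applies no padding.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        padding: str = "valid",
    ):
        if padding not in ("valid", "same"):
            raise ValueError(f"padding must be 'valid' or 'same', got {padding!r}")
        limit = np.sqrt(6.0 / (in_channels * kernel))  # variance-scaling uniform
        self.w = rng.uniform(-limit, limit, (out_channels, in_channels, kernel)).astype(DTYPE)
        self.b = np.zeros(out_channels, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.kernel = kernel
        self.padding = padding
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            right = self.kernel - 1 - left
            x = np.pad(x, ((0, 0), (0, 0), (left, right)))
        x = np.ascontiguousarray(x)
        b, c, length = x.shape
        k_size, f = self.kernel, self.w.shape[0]
        l_out = conv_output_len(length, k_size, 1)
        # im2col in (C*K, B*L_out) orientation -> a single GEMM per layer
        cols = np.empty((c, k_size, b, l_out), dtype=DTYPE)
        for k in range(k_size):
            cols[:, k] = x[:, :, k:k + l_out].transpose(1, 0, 2)
        cols = cols.reshape(c * k_size, b * l_out)
        out = self.w.reshape(f, c * k_size) @ cols
        out = out.reshape(f, b, l_out).transpose(1, 0, 2) + self.b[None, :, None]
        if train:
            self._cols, self._in_shape = cols, (b, c, length)
        return np.ascontiguousarray(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, f, l_out = grad.shape
        _, c, length = self._in_shape
        k_size = self.kernel
        gmat = np.ascontiguousarray(grad.transpose(1, 0, 2)).reshape(f, b * l_out)
        self.gw[...] = (gmat @ self._cols.T).reshape(self.w.shape)
        self.gb[...] = gmat.sum(axis=1)
        gcols = (self.w.reshape(f, c * k_size).T @ gmat).reshape(c, k_size, b, l_out)
        gx = np.zeros((b, c, length), dtype=DTYPE)
        for k in range(k_size):
            gx[:, :, k:k + l_out] += gcols[:, k].transpose(1, 0, 2)
        if self.padding == "same":
            left = (k_size - 1) // 2
            gx = gx[:, :, left:length - (k_size - 1 - left)]
        self._cols = None
        return gx

    def parameters(self) -> list[dict]:
        return [
            {"value": self.w, "grad": self.gw},
            {"value": self.b, "grad": self.gb},
        ]


class BatchNorm1d(Layer):
    """Per-filter normalization over batch and time; running stats at inference."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean[...] = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var[...] = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = grad.shape[0] * grad.shape[2]
        self.ggamma[...] = (grad * xhat).sum(axis=(0, 2))
        self.gbeta[...] = grad.sum(axis=(0, 2))
        g_mean = grad.mean(axis=(0, 2))[None, :, None]
        gx_mean = (grad * xhat).mean(axis=(0, 2))[None, :, None]
        scale = (self.gamma * inv_std)[None, :, None]
        self._cache = None
        return scale * (grad - g_mean - xhat * gx_mean)

    def parameters(self) -> list[dict]:
        return [
            {"value": self.gamma, "grad": self.ggamma},
            {"value": self.beta, "grad": self.gbeta},
        ]

    def state(self) -> dict:
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state: dict) -> None:
        super().load_state(state)
        self.running_mean[...] = state["running_mean"]
        self.running_var[...] = state["running_var"]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0 if train else None
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class MaxPool1d(Layer):
    """Max pooling along time.  ``pool=1`` degenerates to pure subsampling."""

    def __init__(self, pool: int, stride: int):
        if pool < 1 or stride < 1:
            raise ValueError("pool and stride must be >= 1")
        self.pool = pool
        self.stride = stride

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, f, length = x.shape
        l_out = conv_output_len(length, self.pool, self.stride)
        if self.pool == 1:
            out = x[:, :, : l_out * self.stride : self.stride]
            self._cache = (x.shape, None) if train else None
            return np.ascontiguousarray(out)
        span = (l_out - 1) * self.stride + 1
        stacked = np.stack(
            [x[:, :, k:k + span:self.stride] for k in range(self.pool)]
        )  # (pool, B, F, L_out)
        self._cache = (x.shape, stacked.argmax(axis=0)) if train else None
        return stacked.max(axis=0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        shape, idx = self._cache
        self._cache = None
        gx = np.zeros(shape, dtype=DTYPE)
        l_out = grad.shape[2]
        if self.pool == 1:
            gx[:, :, : l_out * self.stride : self.stride] = grad
            return gx
        for k in range(self.pool):
            pos = np.arange(l_out) * self.stride + k
            gx[:, :, pos] += grad * (idx == k)
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / n_in)
        self.w = rng.uniform(-limit, limit, (n_in, n_out)).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        self._x = None
        return grad @ self.w.T

    def parameters(self) -> list[dict]:
        return [
            {"value": self.w, "grad": self.gw},
            {"value": self.b, "grad": self.gb},
        ]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean categorical cross-entropy of integer targets ``y``."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.log(p).mean())


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_until(self, x: np.ndarray, layer_type: type) -> np.ndarray:
        """Forward pass stopping after the first layer of the given type."""
        for layer in self.layers:
            x = layer.forward(x, train=False)
            if isinstance(layer, layer_type):
                return x
        raise ValueError(f"no {layer_type.__name__} layer in model")

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> list[dict]:
        return [p for layer in self.layers for p in layer.parameters()]

    def state_dict(self) -> dict:
        return {i: layer.state() for i, layer in enumerate(self.layers)}

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            layer.load_state(state[i])


class RMSprop:
    """Root-mean-square propagation with Keras-style defaults."""

    def __init__(self, params: list[dict], lr: float, rho: float = 0.9, eps: float = 1e-7):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        for p, c in zip(self.params, self.cache):
            g = p["grad"]
            c[...] = self.rho * c + (1 - self.rho) * g * g
            p["value"][...] -= self.lr * g / (np.sqrt(c) + self.eps)
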