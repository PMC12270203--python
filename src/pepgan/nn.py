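"""Minimal 1-D convolutional neural-network core (numpy, CPU).

Implements exactly the layer vocabulary the adversarial model needs —
1-D convolution, batch normalization, max pooling, linear maps, sigmoid
— with hand-written backward passes and an Adam optimizer.  Every
backward pass is validated against central finite differences in the
test suite.  All randomness flows through an injected numpy Generator,
so training is reproducible bit-for-bit under a fixed seed on one CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "Flatten",
    "Reshape",
    "Linear",
    "Sequential",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=float)
    t = np.asarray(targets, dtype=float)
    # softplus(-z) + (1 - t) * z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, -z) + (1.0 - t) * z))
    grad = (sigmoid(z) - t) / z.size
    return loss, grad


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Cross-correlation over the last axis; ``padding`` zeros each side."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, kernel_size))
        b = np.zeros(out_channels)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.kernel_size = kernel_size
        self.padding = padding

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.padding:
            x = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        self._x = x
        w, b = self.params
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel_size, axis=2)
        self._windows = windows  # (B, Cin, Lout, K)
        return np.einsum("bilk,oik->bol", windows, w, optimize=True) + b[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0] += np.einsum("bilk,bol->oik", self._windows, dy, optimize=True)
        self.grads[1] += dy.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        L_out = dy.shape[2]
        for k in range(self.kernel_size):
            dx[:, :, k : k + L_out] += np.einsum("bol,oi->bil", dy, w[:, :, k], optimize=True)
        if self.padding:
            dx = dx[:, :, self.padding : -self.padding]
        return dx


class BatchNorm1d(Layer):
    """Per-channel normalization over the batch and length axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        gamma = np.ones(channels)
        beta = np.zeros(channels)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        gamma, beta = self.params
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv[None, :, None]
        self._xhat, self._inv, self._train = xhat, inv, train
        return gamma[None, :, None] * xhat + beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        gamma, _ = self.params
        xhat, inv = self._xhat, self._inv
        self.grads[0] += (dy * xhat).sum(axis=(0, 2))
        self.grads[1] += dy.sum(axis=(0, 2))
        dxhat = dy * gamma[None, :, None]
        if not self._train:
            return dxhat * inv[None, :, None]
        n = dy.shape[0] * dy.shape[2]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        return term * inv[None, :, None]


class MaxPool1d(Layer):
    def __init__(self, kernel_size: int = 2) -> None:
        super().__init__()
        self.k = kernel_size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, L = x.shape
        L_out = L // self.k
        xv = x[:, :, : L_out * self.k].reshape(B, C, L_out, self.k)
        self._arg = xv.argmax(axis=3)
        self._shape = x.shape
        return xv.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        L_out = dy.shape[2]
        dx = np.zeros((B, C, L_out, self.k))
        b, c, t = np.ogrid[:B, :C, :L_out]
        dx[b, c, t, self._arg] = dy
        out = np.zeros((B, C, L))
        out[:, :, : L_out * self.k] = dx.reshape(B, C, L_out * self.k)
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(out_features, in_features))
        b = np.zeros(out_features)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        w, b = self.params
        return x @ w.T + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        w, _ = self.params
        self.grads[0] += dy.T @ self._x
        self.grads[1] += dy.sum(axis=0)
        return dy @ w


class Sequential:
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads:
                g.fill(0.0)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(p, g) for layer in self.layers for p, g in zip(layer.params, layer.grads)]

    def state(self) -> dict:
        """Serializable parameter snapshot (including batch-norm stats)."""
        out: dict = {"params": [], "bn": []}
        for layer in self.layers:
            out["params"].append([p.copy() for p in layer.params])
            if isinstance(layer, BatchNorm1d):
                out["bn"].append((layer.running_mean.copy(), layer.running_var.copy()))
        return out

    def load_state(self, state: dict) -> None:
        bn_iter = iter(state["bn"])
        for layer, saved in zip(self.layers, state["params"]):
            for p, s in zip(layer.params, saved):
                p[...] = s
            if isinstance(layer, BatchNorm1d):
                layer.running_mean, layer.running_var = (a.copy() for a in next(bn_iter))


class Adam:
    """Adaptive-momentum optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        parameters: list[tuple[np.ndarray, np.ndarray]],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.parameters = parameters
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in parameters]
        self.v = [np.zeros_like(p) for p, _ in parameters]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (p, g), m, v in zip(self.parameters, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
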