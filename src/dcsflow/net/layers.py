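"""Minimal NumPy neural-network layers with explicit backprop.

Shapes follow the (batch, channels, length) convention.  Each module owns its
parameters and gradients in name-keyed dicts so the optimizer can iterate
over them generically.  Only what the curve regressor needs is implemented:
1-D convolution, batch normalization and the logistic activation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["Conv1d", "BatchNorm1d", "ReLU", "Sigmoid"]


class Module:
    """Base: parameter/gradient registry plus train/eval mode flag."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k] = v.copy()


class Conv1d(Module):
    """1-D convolution (cross-correlation) via an im2col matmul.

    Weight shape (C_out, C_in * k); Glorot-uniform initialized.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None,
                 needs_input_grad: bool = True):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.needs_input_grad = needs_input_grad
        rng = rng or np.random.default_rng()
        fan_in, fan_out = c_in * kernel, c_out * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params["W"] = rng.uniform(-limit, limit,
                                       (c_out, c_in * kernel))
        self.params["b"] = np.zeros(c_out)

    def out_length(self, length: int) -> int:
        n = (length + 2 * self.padding - self.kernel) // self.stride + 1
        if n < 1:
            raise ValueError(
                f"Conv1d(c_in={self.c_in}, k={self.kernel}, s={self.stride}, "
                f"p={self.padding}): input length {length} too short")
        return n

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c_in, length = x.shape
        if c_in != self.c_in:
            raise ValueError(
                f"Conv1d expected {self.c_in} input channels, got {c_in}")
        l_out = self.out_length(length)
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        idx = (np.arange(l_out) * self.stride)[:, None] + np.arange(self.kernel)
        cols = xp[:, :, idx]                       # (n, c_in, l_out, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n, l_out, -1)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, xp.shape, idx)
        return out.transpose(0, 2, 1)              # (n, c_out, l_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xp_shape, idx = self._cache
        n, _, l_out = dout.shape
        dflat = dout.transpose(0, 2, 1).reshape(-1, self.c_out)
        self.grads["W"] = dflat.T @ cols.reshape(-1, cols.shape[-1])
        self.grads["b"] = dflat.sum(axis=0)
        if not self.needs_input_grad:
            return None
        dcols = (dflat @ self.params["W"]).reshape(n, l_out, self.c_in,
                                                   self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)        # (n, c_in, l_out, k)
        dxp = np.zeros(xp_shape)
        starts = np.arange(l_out) * self.stride
        for j in range(self.kernel):               # unique positions per j
            dxp[:, :, starts + j] += dcols[:, :, :, j]
        p = self.padding
        return dxp[:, :, p:dxp.shape[2] - p] if p else dxp


class BatchNorm1d(Module):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        # fused affine: out = a*x + b with per-channel a, b
        a = self.params["gamma"] / std
        b = self.params["beta"] - a * mu
        out = a[None, :, None] * x + b[None, :, None]
        self._cache = (x, mu, std)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, mu, std = self._cache
        xhat = (x - mu[None, :, None]) / std[None, :, None]
        self.grads["gamma"] = np.einsum("ncl,ncl->c", dout, xhat)
        self.grads["beta"] = dout.sum(axis=(0, 2))
        g_over_std = self.params["gamma"] / std
        if not self.training:
            return dout * g_over_std[None, :, None]
        m = dout.shape[0] * dout.shape[2]
        t1 = self.grads["beta"] / m
        t2 = self.grads["gamma"] / m
        return g_over_std[None, :, None] * (dout - t1[None, :, None]
                                            - xhat * t2[None, :, None])

    # running statistics travel with the weights at checkpoint time
    def state(self):
        s = super().state()
        s["running_mean"] = self.running_mean.copy()
        s["running_var"] = self.running_var.copy()
        return s

    def load_state(self, state):
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()
        super().load_state({k: v for k, v in state.items()
                            if k in ("gamma", "beta")})


class ReLU(Module):
    """Rectifier activation."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cache = x > 0
        return x * self._cache

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._cache


class Sigmoid(Module):
    """Logistic activation, numerically symmetric for large |x|."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = expit(x)
        self._cache = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        y = self._cache
        return dout * y * (1.0 - y)
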