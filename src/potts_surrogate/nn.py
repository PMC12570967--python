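"""Minimal fully-connected network with hand-written backprop and Adam.

Kept deliberately small: it only needs to parameterise the denoiser of the
desk-scale diffusion surrogate (and nothing else), so a plain MLP with
SiLU activations, an explicit backward pass and an Adam loop is the whole
story. All randomness flows through an injected numpy Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


def _silu(z: np.ndarray) -> np.ndarray:
    return z / (1.0 + np.exp(-z))


def _silu_grad(z: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-z))
    return s * (1.0 + z * (1.0 - s))


class MLP:
    """Fully-connected net: SiLU hidden layers, linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._cache = None

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        h = x
        zs, hs = [], [h]
        last = len(self.weights) - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            h = z if k == last else _silu(z)
            if cache:
                zs.append(z)
                hs.append(h)
        if cache:
            self._cache = (zs, hs)
        return h

    def backward(self, grad_out: np.ndarray):
        """Gradients of a scalar loss w.r.t. weights/biases given
        dLoss/dOutput; requires a preceding forward(..., cache=True)."""
        if self._cache is None:
            raise RuntimeError("backward() requires forward(cache=True) first")
        zs, hs = self._cache
        g = grad_out
        gw = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        for k in range(len(self.weights) - 1, -1, -1):
            if k != len(self.weights) - 1:
                g = g * _silu_grad(zs[k])
            gw[k] = hs[k].T @ g
            gb[k] = g.sum(axis=0)
            if k > 0:
                g = g @ self.weights[k].T
        self._cache = None
        return gw, gb

    def get_flat(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.weights + self.biases])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for arr in self.weights + self.biases:
            arr[...] = flat[i:i + arr.size].reshape(arr.shape)
            i += arr.size


class Adam:
    """Adaptive-moment estimation over an MLP's parameter list."""

    def __init__(self, net: MLP, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        params = net.weights + net.biases
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads_w, grads_b) -> None:
        self.t += 1
        params = self.net.weights + self.net.biases
        grads = list(grads_w) + list(grads_b)
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
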