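"""Minimal 3-D convolutional network engine (numpy, CPU).

Implements exactly the layer set the segmentation architecture needs — valid
3x3x3 convolutions, 2x2x2 stride-2 strided convolutions, 2x2x2 stride-2
transposed convolutions, 1x1x1 convolutions, leaky ReLU — all with weight
normalisation and hand-derived backward passes, plus an Adam optimiser.
Tensors are single-sample ``(C, D, H, W)`` float32 arrays; batching is an
outer loop with gradient accumulation (patch volumes dominate compute, so
matmul efficiency is unaffected).

Convolutions are evaluated as sums of shifted-view channel matmuls rather
than im2col, keeping peak memory proportional to the activation size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base: parameters in self.params, matching grads in self.grads."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.grads:
            self.grads[k][...] = 0.0


class _WeightNormMixin:
    """W = g * V / ||V||_per-output-channel; He-initialised with g = ||V||."""

    def _init_wn(self, rng, shape, fan_in) -> None:
        V = he_init(rng, shape, fan_in)
        norm = np.sqrt((V.reshape(shape[0], -1) ** 2).sum(axis=1))
        self.params = {"V": V, "g": norm.astype(np.float32),
                       "b": np.zeros(shape[0], dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.weight_norm = True

    def _weight(self) -> np.ndarray:
        V, g = self.params["V"], self.params["g"]
        if not self.weight_norm:
            return V
        flat = V.reshape(V.shape[0], -1)
        self._vnorm = np.sqrt((flat**2).sum(axis=1)) + 1e-12
        return (g / self._vnorm)[(...,) + (None,) * (V.ndim - 1)] * V

    def _weight_grad(self, dW: np.ndarray) -> None:
        V, g = self.params["V"], self.params["g"]
        if not self.weight_norm:
            self.grads["V"] += dW
            return
        n = V.shape[0]
        Vf, dWf = V.reshape(n, -1), dW.reshape(n, -1)
        vnorm = self._vnorm
        unit = Vf / vnorm[:, None]
        dg = (dWf * unit).sum(axis=1)
        dV = (g / vnorm)[:, None] * (dWf - (dWf * unit).sum(axis=1)[:, None] * unit)
        self.grads["g"] += dg.astype(np.float32)
        self.grads["V"] += dV.reshape(V.shape).astype(np.float32)


class ConvValid3(Layer, _WeightNormMixin):
    """3x3x3 convolution, no padding: (Cin, s^3) -> (Cout, (s-2)^3)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 weight_norm: bool = True) -> None:
        super().__init__()
        self._init_wn(rng, (cout, cin, 3, 3, 3), fan_in=cin * 27)
        self.weight_norm = weight_norm

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        W = self._weight()
        self._W = W
        cout = W.shape[0]
        do, ho, wo = (s - 2 for s in x.shape[1:])
        out = np.zeros((cout, do, ho, wo), dtype=np.float32)
        for dz, dy, dx in product(range(3), repeat=3):
            xv = x[:, dz:dz + do, dy:dy + ho, dx:dx + wo]
            out += np.tensordot(W[:, :, dz, dy, dx], xv, axes=([1], [0]))
        out += self.params["b"][:, None, None, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, W = self._x, self._W
        do, ho, wo = gout.shape[1:]
        dW = np.zeros_like(W)
        gin = np.zeros_like(x)
        gf = gout.reshape(gout.shape[0], -1)
        for dz, dy, dx in product(range(3), repeat=3):
            xv = x[:, dz:dz + do, dy:dy + ho, dx:dx + wo]
            dW[:, :, dz, dy, dx] = gf @ xv.reshape(xv.shape[0], -1).T
            gin[:, dz:dz + do, dy:dy + ho, dx:dx + wo] += np.tensordot(
                W[:, :, dz, dy, dx].T, gout, axes=([1], [0])
            )
        self._weight_grad(dW)
        self.grads["b"] += gout.sum(axis=(1, 2, 3))
        return gin


class StridedConv2(Layer, _WeightNormMixin):
    """2x2x2 convolution with stride 2 (the downsampling operator): s -> s/2."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 weight_norm: bool = True) -> None:
        super().__init__()
        self._init_wn(rng, (cout, cin, 2, 2, 2), fan_in=cin * 8)
        self.weight_norm = weight_norm

    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 2 for s in x.shape[1:]):
            raise ValueError(f"odd spatial size {x.shape[1:]} cannot be halved")
        self._x = x
        W = self._weight()
        self._W = W
        do, ho, wo = (s // 2 for s in x.shape[1:])
        out = np.zeros((W.shape[0], do, ho, wo), dtype=np.float32)
        for dz, dy, dx in product(range(2), repeat=3):
            xv = x[:, dz::2, dy::2, dx::2]
            out += np.tensordot(W[:, :, dz, dy, dx], xv, axes=([1], [0]))
        out += self.params["b"][:, None, None, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, W = self._x, self._W
        dW = np.zeros_like(W)
        gin = np.zeros_like(x)
        gf = gout.reshape(gout.shape[0], -1)
        for dz, dy, dx in product(range(2), repeat=3):
            xv = x[:, dz::2, dy::2, dx::2]
            dW[:, :, dz, dy, dx] = gf @ xv.reshape(xv.shape[0], -1).T
            gin[:, dz::2, dy::2, dx::2] += np.tensordot(
                W[:, :, dz, dy, dx].T, gout, axes=([1], [0])
            )
        self._weight_grad(dW)
        self.grads["b"] += gout.sum(axis=(1, 2, 3))
        return gin


class TransposedConv2(Layer, _WeightNormMixin):
    """2x2x2 transposed convolution with stride 2 (upsampling): s -> 2s."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 weight_norm: bool = True) -> None:
        super().__init__()
        self._init_wn(rng, (cout, cin, 2, 2, 2), fan_in=cin)
        self.weight_norm = weight_norm

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        W = self._weight()
        self._W = W
        d, h, w = x.shape[1:]
        out = np.zeros((W.shape[0], 2 * d, 2 * h, 2 * w), dtype=np.float32)
        for dz, dy, dx in product(range(2), repeat=3):
            out[:, dz::2, dy::2, dx::2] = np.tensordot(
                W[:, :, dz, dy, dx], x, axes=([1], [0])
            )
        out += self.params["b"][:, None, None, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, W = self._x, self._W
        dW = np.zeros_like(W)
        gin = np.zeros_like(x)
        xf = x.reshape(x.shape[0], -1)
        for dz, dy, dx in product(range(2), repeat=3):
            gv = gout[:, dz::2, dy::2, dx::2]
            dW[:, :, dz, dy, dx] = gv.reshape(gv.shape[0], -1) @ xf.T
            gin += np.tensordot(W[:, :, dz, dy, dx].T, gv, axes=([1], [0]))
        self._weight_grad(dW)
        self.grads["b"] += gout.sum(axis=(1, 2, 3))
        return gin


class Conv1x1(Layer, _WeightNormMixin):
    """Pointwise convolution; ``linear=True`` leaves logits unactivated."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 weight_norm: bool = True) -> None:
        super().__init__()
        self._init_wn(rng, (cout, cin), fan_in=cin)
        self.weight_norm = weight_norm

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        W = self._weight()
        self._W = W
        out = np.tensordot(W, x, axes=([1], [0]))
        out += self.params["b"][:, None, None, None]
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        x, W = self._x, self._W
        gf = gout.reshape(gout.shape[0], -1)
        dW = gf @ x.reshape(x.shape[0], -1).T
        self._weight_grad(dW)
        self.grads["b"] += gout.sum(axis=(1, 2, 3))
        return np.tensordot(W.T, gout, axes=([1], [0]))


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        out = x.copy()
        out[self._neg] *= self.slope
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        gin = gout.copy()
        gin[self._neg] *= self.slope
        return gin


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def center_crop(x: np.ndarray, target_side: int) -> np.ndarray:
    """Symmetric spatial crop of (C, s, s, s) to (C, t, t, t); s-t must be even."""
    s = x.shape[1]
    if s == target_side:
        return x
    d = s - target_side
    if d < 0 or d % 2:
        raise ValueError(f"cannot center-crop {s} to {target_side}")
    a = d // 2
    return x[:, a:s - a, a:s - a, a:s - a]


@dataclass
class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    state: dict = field(default_factory=dict)

    def step(self, layers: list[Layer]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for i, layer in enumerate(layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                key = (i, k)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
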