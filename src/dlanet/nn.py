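"""Minimal NumPy neural-network layers with explicit backpropagation.

The zone classifiers are small enough to train on one CPU, so the layers
below implement forward and backward passes directly on NHWC float64
arrays. Gradients of every layer are validated against central finite
differences in the test suite.

Layers: strided SAME-padded 2-D convolution, ReLU, global average pooling,
dense, and the three attention gate layers (channel, spatial, and the
parallel dual gate) matching the functional definitions in
:mod:`dlanet.attention`.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .attention import SA_KERNEL_SIZE, hidden_size
from .errors import ParameterError


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class Layer:
    params: List[Param]

    def __init__(self):
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _same_pads(size: int, stride: int, ksize: int) -> Tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for SAME padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + ksize - size, 0)
    return out, total // 2, total - total // 2


class Conv2D(Layer):
    """k x k convolution, SAME zero padding, arbitrary stride, NHWC."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.ksize, self.stride = ksize, stride
        w = rng.standard_normal((ksize, ksize, in_ch, out_ch)) * np.sqrt(2.0 / (ksize * ksize * in_ch))
        self.w = Param("conv_w", w)
        self.b = Param("conv_b", np.zeros(out_ch))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        ho, pt, pb = _same_pads(h, self.stride, self.ksize)
        wo, pl, pr = _same_pads(w, self.stride, self.ksize)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        out = np.broadcast_to(self.b.value, (b, ho, wo, self.b.size)).copy()
        s = self.stride
        for di in range(self.ksize):
            for dj in range(self.ksize):
                xs = xp[:, di : di + ho * s : s, dj : dj + wo * s : s, :]
                out += xs @ self.w.value[di, dj]
        self._cache = (xp, (h, w), (pt, pl), (ho, wo))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp, (h, w), (pt, pl), (ho, wo) = self._cache
        s = self.stride
        self.b.grad += grad.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        for di in range(self.ksize):
            for dj in range(self.ksize):
                xs = xp[:, di : di + ho * s : s, dj : dj + wo * s : s, :]
                self.w.grad[di, dj] += np.tensordot(xs, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += grad @ self.w.value[di, dj].T
        return dxp[:, pt : pt + h, pl : pl + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class GlobalAvgPool(Layer):
    """NHWC -> NC mean over the spatial grid."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :], self._shape) / (h * w)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = Param("dense_w", rng.standard_normal((in_dim, out_dim)) * np.sqrt(2.0 / in_dim))
        self.b = Param("dense_b", np.zeros(out_dim))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T


class ChannelGate(Layer):
    """Squeeze-and-excitation channel gate (trainable CA layer)."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        h = hidden_size(channels, ratio)
        self.ratio = ratio
        self.w0 = Param("ca_w0", rng.standard_normal((h, channels)) * np.sqrt(2.0 / channels))
        self.b0 = Param("ca_b0", np.zeros(h))
        self.w1 = Param("ca_w1", rng.standard_normal((channels, h)) * np.sqrt(2.0 / h))
        self.b1 = Param("ca_b1", np.zeros(channels))
        self.params = [self.w0, self.b0, self.w1, self.b1]

    def _gate(self, x: np.ndarray):
        z = x.mean(axis=(1, 2))                       # (B, C)
        u = z @ self.w0.value.T + self.b0.value       # (B, h)
        hdn = np.maximum(u, 0.0)
        v = hdn @ self.w1.value.T + self.b1.value     # (B, C)
        a = _sigmoid(v)
        return z, u, hdn, a

    def _gate_backward(self, x: np.ndarray, z, u, hdn, a, da: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. x of the gate path given dL/da; accumulates param grads."""
        b, h, w, c = x.shape
        dv = da * a * (1.0 - a)
        self.w1.grad += dv.T @ hdn
        self.b1.grad += dv.sum(axis=0)
        dhdn = dv @ self.w1.value
        du = dhdn * (u > 0)
        self.w0.grad += du.T @ z
        self.b0.grad += du.sum(axis=0)
        dz = du @ self.w0.value
        return np.broadcast_to(dz[:, None, None, :], x.shape) / (h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        z, u, hdn, a = self._gate(x)
        self._cache = (x, z, u, hdn, a)
        return x * a[:, None, None, :]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, u, hdn, a = self._cache
        da = (grad * x).sum(axis=(1, 2))
        dx = grad * a[:, None, None, :]
        dx += self._gate_backward(x, z, u, hdn, a, da)
        return dx


class SpatialGate(Layer):
    """7x7-convolution spatial gate over [avg, max] channel descriptors."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2D(2, 1, SA_KERNEL_SIZE, 1, rng)
        self.conv.w.name, self.conv.b.name = "sa_kernel", "sa_bias"
        self.params = self.conv.params

    def _gate(self, x: np.ndarray):
        avg = x.mean(axis=3)
        idx = x.argmax(axis=3)
        mx = np.take_along_axis(x, idx[..., None], axis=3)[..., 0]
        d = np.stack([avg, mx], axis=-1)              # (B, H, W, 2)
        score = self.conv.forward(d)[..., 0]
        a = _sigmoid(score)
        return idx, a

    def _gate_backward(self, x: np.ndarray, idx, a, da: np.ndarray) -> np.ndarray:
        ds = da * a * (1.0 - a)
        dd = self.conv.backward(ds[..., None])
        dx = np.broadcast_to(dd[..., 0:1], x.shape) / x.shape[3]
        dmx = np.zeros_like(x)
        np.put_along_axis(dmx, idx[..., None], dd[..., 1:2], axis=3)
        return dx + dmx

    def forward(self, x: np.ndarray) -> np.ndarray:
        idx, a = self._gate(x)
        self._cache = (x, idx, a)
        return x * a[..., None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, idx, a = self._cache
        da = (grad * x).sum(axis=3)
        dx = grad * a[..., None]
        dx += self._gate_backward(x, idx, a, da)
        return dx


class ParallelDualGate(Layer):
    """Channel and spatial gates both computed from the raw input and applied jointly."""

    def __init__(self, channels: int, ratio: int, rng: np.random.Generator):
        super().__init__()
        self.cg = ChannelGate(channels, ratio, rng)
        self.sg = SpatialGate(rng)
        self.params = self.cg.params + self.sg.params

    def forward(self, x: np.ndarray) -> np.ndarray:
        z, u, hdn, a_c = self.cg._gate(x)
        idx, a_s = self.sg._gate(x)
        self._cache = (x, z, u, hdn, a_c, idx, a_s)
        return x * a_c[:, None, None, :] * a_s[..., None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, z, u, hdn, a_c, idx, a_s = self._cache
        gc = a_c[:, None, None, :]
        gs = a_s[..., None]
        dx = grad * gc * gs
        da_c = (grad * x * gs).sum(axis=(1, 2))
        da_s = (grad * x * gc).sum(axis=3)
        dx += self.cg._gate_backward(x, z, u, hdn, a_c, da_c)
        dx += self.sg._gate_backward(x, idx, a_s, da_s)
        return dx


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


class SequentialModel:
    """A plain stack of layers ending in a dense logits layer."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    # -- forward / training -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [softmax(self.forward(x[i : i + batch_size])) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
        """Mean cross-entropy over the batch; accumulates parameter grads."""
        logits = self.forward(x)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        grad = probs.copy()
        grad[np.arange(len(y)), y] -= 1.0
        grad /= len(y)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return loss, probs

    # -- parameter handling -------------------------------------------------
    def parameters(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ParameterError("weight list does not match model parameters")
        for p, w in zip(params, weights):
            if p.value.shape != w.shape:
                raise ParameterError(f"shape mismatch for {p.name}: {p.value.shape} vs {w.shape}")
            p.value[...] = w

    def save_weights(self, path) -> None:
        np.savez(path, **{f"p{i}": w for i, w in enumerate(self.get_weights())})

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.set_weights([data[f"p{i}"] for i in range(len(data.files))])


class Adam:
    """Adam optimiser with a mutable learning rate (for plateau reduction)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
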