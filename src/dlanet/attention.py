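"""Dual lesion attention: channel and spatial gates over a feature map.

The feature map ``F`` is a rank-3 tensor H x W x C (the deepest backbone
output). Channel attention (CA) is a squeeze-and-excitation gate:

    A_c = sigmoid(W1 . relu(W0 . mean_{h,w} F + b0) + b1)      (length C)

with a bottleneck of size ``max(1, floor(C / r))`` set by the compression
ratio ``r`` (default 16). The bias vectors default to zero; with zero biases
the expression reduces to the bare two-layer form. The inner rectifier
follows the squeeze-and-excitation convention.

Spatial attention (SA) pools the (channel-refined) map over channels into an
average map and a max map, stacks them as a 2-channel descriptor, and passes
a single 7x7 convolution with SAME zero padding:

    A_s = sigmoid(conv7x7([avg, max]) + bias)                  (H x W)

Gates are applied by broadcast multiplication; every gate value lies
strictly in (0, 1). Composition variants: ``none`` (identity), ``ca``,
``sa``, ``sequential`` (CA then SA computed from the channel-refined map —
the default), and ``parallel`` (both gates computed from the raw map and
applied jointly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import correlate

from .errors import ParameterError

VARIANTS: Tuple[str, ...] = ("none", "ca", "sa", "sequential", "parallel")
_VARIANT_ALIASES = {"ca_only": "ca", "sa_only": "sa"}

SA_KERNEL_SIZE = 7


def canonical_variant(variant: str) -> str:
    v = _VARIANT_ALIASES.get(variant, variant)
    if v not in VARIANTS:
        raise ParameterError(f"unknown attention variant {variant!r}; expected one of {VARIANTS}")
    return v


def hidden_size(channels: int, ratio: int) -> int:
    """Bottleneck width of the CA multilayer perceptron."""
    if ratio < 1:
        raise ParameterError("compression ratio must be a positive integer")
    return max(1, channels // ratio)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ChannelAttentionParams:
    """Weights of the CA excitation MLP: w0 (h x C), w1 (C x h), ratio r."""

    w0: np.ndarray
    w1: np.ndarray
    ratio: int = 16
    b0: Optional[np.ndarray] = None
    b1: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.w0 = np.asarray(self.w0, dtype=float)
        self.w1 = np.asarray(self.w1, dtype=float)
        if self.w0.ndim != 2 or self.w1.ndim != 2:
            raise ParameterError("w0 and w1 must be matrices")
        h, c = self.w0.shape
        if self.w1.shape != (c, h):
            raise ParameterError(f"w1 shape {self.w1.shape} inconsistent with w0 shape {self.w0.shape}")
        if h != hidden_size(c, self.ratio):
            raise ParameterError(
                f"hidden size {h} does not match max(1, floor({c}/{self.ratio}))"
            )
        self.b0 = np.zeros(h) if self.b0 is None else np.asarray(self.b0, dtype=float)
        self.b1 = np.zeros(c) if self.b1 is None else np.asarray(self.b1, dtype=float)
        if self.b0.shape != (h,) or self.b1.shape != (c,):
            raise ParameterError("bias shapes inconsistent with w0/w1")

    @property
    def channels(self) -> int:
        return self.w0.shape[1]

    @classmethod
    def initialise(cls, channels: int, ratio: int, rng: np.random.Generator) -> "ChannelAttentionParams":
        """Fan-in-scaled random init with zero biases."""
        h = hidden_size(channels, ratio)
        w0 = rng.standard_normal((h, channels)) * np.sqrt(2.0 / channels)
        w1 = rng.standard_normal((channels, h)) * np.sqrt(2.0 / h)
        return cls(w0=w0, w1=w1, ratio=ratio)

    @classmethod
    def zeros(cls, channels: int, ratio: int = 16) -> "ChannelAttentionParams":
        h = hidden_size(channels, ratio)
        return cls(w0=np.zeros((h, channels)), w1=np.zeros((channels, h)), ratio=ratio)


@dataclass
class SpatialAttentionParams:
    """Weights of the SA 7x7 convolution over the 2-channel descriptor."""

    kernel: np.ndarray
    bias: float = 0.0

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        if self.kernel.shape != (SA_KERNEL_SIZE, SA_KERNEL_SIZE, 2):
            raise ParameterError(f"SA kernel must be {SA_KERNEL_SIZE}x{SA_KERNEL_SIZE}x2, got {self.kernel.shape}")
        self.bias = float(self.bias)

    @classmethod
    def initialise(cls, rng: np.random.Generator) -> "SpatialAttentionParams":
        fan_in = SA_KERNEL_SIZE * SA_KERNEL_SIZE * 2
        return cls(kernel=rng.standard_normal((SA_KERNEL_SIZE, SA_KERNEL_SIZE, 2)) * np.sqrt(2.0 / fan_in))

    @classmethod
    def zeros(cls) -> "SpatialAttentionParams":
        return cls(kernel=np.zeros((SA_KERNEL_SIZE, SA_KERNEL_SIZE, 2)), bias=0.0)


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ParameterError(f"feature map must be rank-3 (H, W, C), got shape {f.shape}")
    if not np.isfinite(f).all():
        raise ParameterError("feature map contains non-finite entries")
    return f


def channel_squeeze(f: np.ndarray) -> np.ndarray:
    """Global average pooling: per-channel mean over all spatial positions."""
    return _check_feature_map(f).mean(axis=(0, 1))


def channel_attention(f: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Channel gate A_c in (0, 1)^C from the squeezed descriptor."""
    f = _check_feature_map(f)
    if params.channels != f.shape[2]:
        raise ParameterError(f"params expect C={params.channels}, feature map has C={f.shape[2]}")
    z = channel_squeeze(f)
    hidden = np.maximum(params.w0 @ z + params.b0, 0.0)
    return _sigmoid(params.w1 @ hidden + params.b1)


def apply_channel(f: np.ndarray, a_c: np.ndarray) -> np.ndarray:
    """Broadcast the channel gate along the spatial dimensions."""
    f = _check_feature_map(f)
    a_c = np.asarray(a_c, dtype=float)
    if a_c.shape != (f.shape[2],):
        raise ParameterError(f"channel gate length {a_c.shape} != C={f.shape[2]}")
    return f * a_c[None, None, :]


def spatial_descriptors(f: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(average map, max map): per-position mean and max over channels."""
    f = _check_feature_map(f)
    return f.mean(axis=2), f.max(axis=2)


def spatial_attention(f: np.ndarray, params: SpatialAttentionParams) -> np.ndarray:
    """Spatial gate A_s in (0, 1)^{H x W} via the 7x7 SAME-padded convolution."""
    avg_map, max_map = spatial_descriptors(f)
    score = (
        correlate(avg_map, params.kernel[:, :, 0], mode="constant", cval=0.0)
        + correlate(max_map, params.kernel[:, :, 1], mode="constant", cval=0.0)
        + params.bias
    )
    return _sigmoid(score)


def apply_spatial(f: np.ndarray, a_s: np.ndarray) -> np.ndarray:
    """Broadcast the spatial gate across the channel dimension."""
    f = _check_feature_map(f)
    a_s = np.asarray(a_s, dtype=float)
    if a_s.shape != f.shape[:2]:
        raise ParameterError(f"spatial gate shape {a_s.shape} != (H, W)={f.shape[:2]}")
    return f * a_s[:, :, None]


def dla(
    f: np.ndarray,
    ca: ChannelAttentionParams,
    sa: SpatialAttentionParams,
    variant: str = "sequential",
) -> np.ndarray:
    """Apply the dual-attention refinement in the requested composition.

    sequential: SA is computed from the channel-refined map (the default
    architecture); parallel: both gates are computed from the raw input and
    applied as a joint broadcast product.
    """
    f = _check_feature_map(f)
    v = canonical_variant(variant)
    if v == "none":
        return f.copy()
    if v == "ca":
        return apply_channel(f, channel_attention(f, ca))
    if v == "sa":
        return apply_spatial(f, spatial_attention(f, sa))
    if v == "sequential":
        f_c = apply_channel(f, channel_attention(f, ca))
        return apply_spatial(f_c, spatial_attention(f_c, sa))
    # parallel
    a_c = channel_attention(f, ca)
    a_s = spatial_attention(f, sa)
    return f * a_c[None, None, :] * a_s[:, :, None]
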