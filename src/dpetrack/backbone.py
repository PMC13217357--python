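"""Convolutional feature extractor with Fourier-KAN adaptive kernels.

The backbone follows a Kolmogorov–Arnold design: instead of a single scalar
weight per (input, output) channel pair, each connection carries a learnable
univariate function, here a truncated Fourier series

    phi(x) = sum_{k=1..G} a_k cos(k·s·x) + b_k sin(k·s·x)

with ``G`` harmonics and an input scale ``s`` that maps normalised feature
values into a bounded angular domain.  A plain two-stride convolutional stem
reduces the image to 1/4 resolution before the FT-KAN blocks; two further
stride-2 convolutions give a three-level pyramid at strides 4, 8 and 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Module, Parameter, Tensor, im2col

__all__ = [
    "FourierKanSpec",
    "FeaturePyramid",
    "ftkan_activation",
    "ftkan_activation_grad",
    "Conv2d",
    "FTKANConv2d",
    "Backbone",
    "backbone_forward",
]


@dataclass
class FourierKanSpec:
    """Coefficients of one bank of Fourier-series activations.

    ``a`` and ``b`` have shape (in_features, out_channels, G): one length-G
    harmonic vector per (input, output) channel pair.
    """

    order: int
    in_channels: int
    out_channels: int
    a: np.ndarray
    b: np.ndarray
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("harmonic order G must be >= 1")
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValueError("FT-KAN coefficients must be finite")

    @classmethod
    def random(cls, order: int, in_channels: int, out_channels: int,
               input_scale: float, rng: np.random.Generator) -> "FourierKanSpec":
        # variance-preserving init: each output sums in_channels·G terms
        sd = 1.0 / np.sqrt(in_channels * order)
        shape = (in_channels, out_channels, order)
        return cls(order, in_channels, out_channels,
                   a=rng.normal(0, sd, shape), b=rng.normal(0, sd, shape),
                   input_scale=input_scale)


def ftkan_activation(x, spec: FourierKanSpec, pair: tuple[int, int] = (0, 0)) -> float:
    """Evaluate one channel pair's Fourier activation at scalar (or array) x."""
    i, o = pair
    a, b = spec.a[i, o], spec.b[i, o]
    k = np.arange(1, spec.order + 1)
    ang = np.multiply.outer(np.asarray(x, dtype=float), k) * spec.input_scale
    val = np.cos(ang) @ a + np.sin(ang) @ b
    return float(val) if np.isscalar(x) or np.asarray(x).ndim == 0 else val


def ftkan_activation_grad(x: float, spec: FourierKanSpec,
                          pair: tuple[int, int] = (0, 0)):
    """Analytic gradients of :func:`ftkan_activation` at scalar x.

    Returns ``(d_a, d_b, d_x)``: gradients w.r.t. the coefficient vectors
    and the input.
    """
    i, o = pair
    a, b = spec.a[i, o], spec.b[i, o]
    k = np.arange(1, spec.order + 1)
    s = spec.input_scale
    ang = k * s * x
    d_a = np.cos(ang)
    d_b = np.sin(ang)
    d_x = float(np.sum(-a * k * s * np.sin(ang) + b * k * s * np.cos(ang)))
    return d_a, d_b, d_x


@dataclass
class FeaturePyramid:
    """Multiscale features: list of (stride, channels, map) triples.

    ``levels[i][2]`` is a (C, H_i, W_i) array (or Tensor during training);
    strides increase strictly.  The source image is kept for contour stages
    that need raw intensities (landmark extraction, profile evolution).
    """

    levels: list
    image: np.ndarray | None = None

    def __post_init__(self) -> None:
        strides = [lvl[0] for lvl in self.levels]
        if any(s2 <= s1 for s1, s2 in zip(strides, strides[1:])):
            raise ValueError("pyramid strides must strictly increase")

    def level(self, stride: int):
        for s, _, fmap in self.levels:
            if s == stride:
                return fmap
        raise KeyError(f"no pyramid level at stride {stride}")


class Conv2d(Module):
    """Plain k×k convolution via patch extraction + matmul."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, k // 2
        fan_in = c_in * k * k
        w = np.zeros((fan_in, c_out)) if zero_init else \
            rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        cols = im2col(x, self.k, self.stride, self.pad)     # B,Ho,Wo,F
        y = cols @ self.W + self.b
        return y.transpose(0, 3, 1, 2)                      # B,C,Ho,Wo


class FTKANConv2d(Module):
    """Convolution whose per-weight nonlinearity is a learnable Fourier series.

    Each output channel sums, over every input channel and every cell of the
    k×k window, a truncated Fourier series of the input value — the FT-KAN
    scheme.  With all coefficients zero the layer outputs zero everywhere.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, order: int = 3,
                 input_scale: float = np.pi, stride: int = 1,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.pad = k, stride, k // 2
        self.order, self.input_scale = order, input_scale
        fan_in = c_in * k * k
        spec = FourierKanSpec.random(order, fan_in, c_out, input_scale, rng)
        if zero_init:
            spec.a[:] = 0.0
            spec.b[:] = 0.0
        # stored as (G, F, C_out) for harmonic-wise matmul
        self.A = Parameter(spec.a.transpose(2, 0, 1).copy())
        self.B = Parameter(spec.b.transpose(2, 0, 1).copy())
        self.bias = Parameter(np.zeros(c_out))

    def spec(self) -> FourierKanSpec:
        return FourierKanSpec(self.order, self.A.data.shape[1], self.A.data.shape[2],
                              a=self.A.data.transpose(1, 2, 0),
                              b=self.B.data.transpose(1, 2, 0),
                              input_scale=self.input_scale)

    def __call__(self, x: Tensor) -> Tensor:
        cols = im2col(x, self.k, self.stride, self.pad)     # B,Ho,Wo,F
        y = None
        for g in range(1, self.order + 1):
            ang = cols * (g * self.input_scale)
            term = ang.cos() @ self.A[g - 1] + ang.sin() @ self.B[g - 1]
            y = term if y is None else y + term
        y = y + self.bias
        return y.transpose(0, 3, 1, 2)


def ftkan_conv(fmap: np.ndarray, layer: FTKANConv2d) -> np.ndarray:
    """Inference-mode FT-KAN convolution of a (C, H, W) array."""
    x = Tensor(np.asarray(fmap, dtype=float)[None])
    return layer(x).data[0]


class Backbone(Module):
    """Stem + FT-KAN blocks producing a 3-level pyramid at strides 4/8/16."""

    def __init__(self, channels: tuple[int, int, int] = (16, 32, 64),
                 order: int = 3, input_scale: float = np.pi, seed: int = 0):
        rng = np.random.default_rng(seed)
        c1, c2, c3 = channels
        self.channels = channels
        self.stem1 = Conv2d(1, c1, k=3, stride=2, rng=rng)
        self.stem2 = Conv2d(c1, c1, k=3, stride=2, rng=rng)
        self.kan4 = FTKANConv2d(c1, c1, k=3, order=order,
                                input_scale=input_scale, rng=rng)
        self.down8 = Conv2d(c1, c2, k=3, stride=2, rng=rng)
        self.kan8 = FTKANConv2d(c2, c2, k=3, order=order,
                                input_scale=input_scale, rng=rng)
        self.down16 = Conv2d(c2, c3, k=3, stride=2, rng=rng)

    def forward_tensor(self, images: Tensor) -> list[Tensor]:
        """(B, 1, H, W) in [0, 1] -> feature tensors at strides 4, 8, 16."""
        h = self.stem1(images).relu()
        h = self.stem2(h).relu()
        p4 = h + self.kan4(h.tanh())        # residual FT-KAN block
        h8 = self.down8(p4).relu()
        p8 = h8 + self.kan8(h8.tanh())
        p16 = self.down16(p8).relu()
        return [p4, p8, p16]

    def __call__(self, image: np.ndarray) -> FeaturePyramid:
        img = np.asarray(image, dtype=float)
        if img.ndim != 2:
            raise ValueError("backbone expects a single 2D grayscale frame")
        if min(img.shape) < 16:
            raise ValueError("image must be at least 16 px on each side")
        x = Tensor(img[None, None])
        p4, p8, p16 = self.forward_tensor(x)
        c1, c2, c3 = self.channels
        return FeaturePyramid(
            levels=[(4, c1, p4.data[0]), (8, c2, p8.data[0]), (16, c3, p16.data[0])],
            image=img,
        )


def backbone_forward(image: np.ndarray, backbone: Backbone | None = None,
                     seed: int = 0) -> FeaturePyramid:
    """Run a (possibly freshly initialised) backbone on one grayscale frame."""
    bb = backbone or Backbone(seed=seed)
    return bb(image)
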