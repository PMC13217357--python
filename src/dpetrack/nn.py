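"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable pieces of this package (Fourier-KAN convolutions, the
detection and contour-offset heads, the tracking GNN) are small — a few
thousand parameters — so they run on a compact tape-based autodiff layer
rather than a deep-learning framework.  Only the operations those modules
need are implemented: broadcast arithmetic, matmul, trigonometric and
sigmoid-family nonlinearities, reductions, reshaping, patch extraction for
convolutions, and bilinear map sampling.

Everything is float64 and single-threaded, which makes training bitwise
reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Module", "Linear", "Adam", "SGD",
           "concat", "stack", "im2col", "bilinear_sample"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return self._op(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return self._op(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return self._op(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data ** 2, b.data.shape))
        return self._op(self.data / other.data, (self, other), bwd)

    def __pow__(self, p: float):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))
        return self._op(self.data ** p, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        return self._op(self.data @ other.data, (self, other), bwd)

    __matmul__ = matmul

    # -- nonlinearities -------------------------------------------------------
    def sin(self):
        def bwd(g, a=self):
            a._accum(g * np.cos(a.data))
        return self._op(np.sin(self.data), (self,), bwd)

    def cos(self):
        def bwd(g, a=self):
            a._accum(-g * np.sin(a.data))
        return self._op(np.cos(self.data), (self,), bwd)

    def tanh(self):
        y = np.tanh(self.data)
        def bwd(g, a=self, y=y):
            a._accum(g * (1.0 - y * y))
        return self._op(y, (self,), bwd)

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        def bwd(g, a=self, y=y):
            a._accum(g * y * (1.0 - y))
        return self._op(y, (self,), bwd)

    def relu(self):
        m = self.data > 0
        def bwd(g, a=self, m=m):
            a._accum(g * m)
        return self._op(self.data * m, (self,), bwd)

    def exp(self):
        y = np.exp(self.data)
        def bwd(g, a=self, y=y):
            a._accum(g * y)
        return self._op(y, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)
        return self._op(np.log(self.data), (self,), bwd)

    # -- shape / reduction ----------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        def bwd(g, a=self, orig=orig):
            a._accum(g.reshape(orig))
        return self._op(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        def bwd(g, a=self, inv=inv):
            a._accum(g.transpose(*inv))
        return self._op(self.data.transpose(*axes), (self,), bwd)

    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())
        return self._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        def bwd(g, a=self, idx=idx):
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)
        return self._op(self.data[idx], (self,), bwd)

    # -- autograd driver ------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bwd(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])
    return Tensor._op(data, tuple(tensors), bwd)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    data = np.stack([t.data for t in tensors], axis=axis)
    def bwd(g, tensors=tensors, axis=axis):
        parts = np.moveaxis(g, axis, 0)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)
    return Tensor._op(data, tuple(tensors), bwd)


def im2col(x: Tensor, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Extract k×k patches from a (B, C, H, W) tensor.

    Returns (B, Ho, Wo, C*k*k); the channel-major flattening matches the
    weight layout of :class:`~dpetrack.backbone.Conv2d`.
    """
    B, C, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # B, C, Ho, Wo, k, k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * k * k).copy()

    def bwd(g, x=x, k=k, stride=stride, pad=pad, B=B, C=C,
            Hp=Hp, Wp=Wp, Ho=Ho, Wo=Wo):
        gx = np.zeros((B, C, Hp, Wp))
        gw = g.reshape(B, Ho, Wo, C, k, k)
        for di in range(k):
            for dj in range(k):
                gx[:, :, di:di + Ho * stride:stride, dj:dj + Wo * stride:stride] += \
                    gw[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if pad:
            gx = gx[:, :, pad:Hp - pad, pad:Wp - pad]
        x._accum(gx)

    return Tensor._op(cols, (x,), bwd)


def bilinear_sample(fmap: Tensor, pts: Tensor, stride: float = 1.0) -> Tensor:
    """Sample a (C, H, W) feature map at sub-pixel image points.

    ``pts`` is (N, 2) in image (x, y) pixels; ``stride`` converts image
    pixels to feature-map cells.  Coordinates are clamped to the map border.
    Gradients flow to both the feature map and the points.
    """
    C, H, W = fmap.data.shape
    p = pts.data / stride
    x = np.clip(p[:, 0], 0.0, W - 1.0)
    y = np.clip(p[:, 1], 0.0, H - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, W - 2) if W > 1 else np.zeros(len(x), int)
    y0 = np.clip(np.floor(y).astype(int), 0, H - 2) if H > 1 else np.zeros(len(y), int)
    x1, y1 = x0 + (1 if W > 1 else 0), y0 + (1 if H > 1 else 0)
    fx, fy = x - x0, y - y0
    f = fmap.data
    val = (f[:, y0, x0] * (1 - fx) * (1 - fy) + f[:, y0, x1] * fx * (1 - fy)
           + f[:, y1, x0] * (1 - fx) * fy + f[:, y1, x1] * fx * fy).T  # (N, C)

    def bwd(g, fmap=fmap, pts=pts):
        gT = g.T  # (C, N)
        if fmap.requires_grad:
            gf = np.zeros_like(fmap.data)
            np.add.at(gf, (slice(None), y0, x0), gT * (1 - fx) * (1 - fy))
            np.add.at(gf, (slice(None), y0, x1), gT * fx * (1 - fy))
            np.add.at(gf, (slice(None), y1, x0), gT * (1 - fx) * fy)
            np.add.at(gf, (slice(None), y1, x1), gT * fx * fy)
            fmap._accum(gf)
        if pts.requires_grad:
            dvdx = ((f[:, y0, x1] - f[:, y0, x0]) * (1 - fy)
                    + (f[:, y1, x1] - f[:, y1, x0]) * fy)      # (C, N)
            dvdy = ((f[:, y1, x0] - f[:, y0, x0]) * (1 - fx)
                    + (f[:, y1, x1] - f[:, y0, x1]) * fx)
            gp = np.zeros_like(pts.data)
            gp[:, 0] = (gT * dvdx).sum(axis=0) / stride
            gp[:, 1] = (gT * dvdy).sum(axis=0) / stride
            pts._accum(gp)

    return Tensor._op(val, (fmap, pts), bwd)


class Module:
    """Base class holding named parameters; supports nested modules."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def named_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                out[key] = v.data
            elif isinstance(v, Module):
                out.update(v.named_arrays(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_arrays(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{key}.{i}"] = item.data
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                v.data = np.asarray(arrays[key], dtype=float).reshape(v.data.shape)
            elif isinstance(v, Module):
                v.load_arrays(arrays, prefix=key + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_arrays(arrays, prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        item.data = np.asarray(arrays[f"{key}.{i}"], float).reshape(item.data.shape)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Linear(Module):
    """Affine map y = x W + b with He-scaled random init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class SGD:
    def __init__(self, params: list[Parameter], lr: float):
        self.params, self.lr = params, lr

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    def __init__(self, params: list[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params, self.lr = params, lr
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
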