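"""Minimal reverse-mode automatic differentiation on numpy arrays.

A ``Tensor`` wraps an ndarray and records vector-Jacobian products
toward its parents; ``Tensor.backward()`` runs the reverse sweep in
topological order.  Only the operations the volumetric networks and the
L1 + 3D-SSIM loss require are implemented: broadcast-aware arithmetic,
ReLU, |.|, reductions, channel concatenation, factor-2 average pooling
and linear upsampling, and separable fixed-kernel Gaussian blur (the
SSIM window; self-adjoint for a symmetric kernel under zero padding).
Convolution with *learned* kernels lives in `hemipact.nn.layers`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "Tensor",
    "concat",
    "relu",
    "leaky_relu",
    "mean_abs",
    "avgpool2",
    "upsample2_linear",
    "gauss_blur3d",
]


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_vjps")

    def __init__(self, data, requires_grad: bool = False, _vjps=()):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in _vjps)
        self.grad = None
        self._vjps = tuple((p, fn) for p, fn in _vjps if p.requires_grad)

    # -- graph ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._vjps:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, fn in node._vjps:
                g = fn(node.grad)
                if parent.grad is None:
                    parent.grad = g.astype(parent.data.dtype, copy=True)
                else:
                    parent.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- basic properties --------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data + other.data,
            _vjps=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data - other.data,
            _vjps=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(-g, other.data.shape)),
            ),
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            _vjps=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        denom = other.data
        return Tensor(
            self.data / denom,
            _vjps=(
                (self, lambda g: _unbroadcast(g / denom, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(-g * self.data / denom**2, other.data.shape),
                ),
            ),
        )

    def __neg__(self):
        return Tensor(-self.data, _vjps=((self, lambda g: -g),))

    def square(self):
        return Tensor(self.data**2, _vjps=((self, lambda g: g * 2.0 * self.data),))

    def mean(self):
        n = self.data.size
        return Tensor(
            np.asarray(self.data.mean()),
            _vjps=((self, lambda g: np.broadcast_to(g / n, self.data.shape).copy()),),
        )

    def sum(self):
        return Tensor(
            np.asarray(self.data.sum()),
            _vjps=((self, lambda g: np.broadcast_to(g, self.data.shape).copy()),),
        )


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0.0), _vjps=((x, lambda g: g * mask),))


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    factor = np.where(mask, 1.0, slope)
    return Tensor(x.data * factor, _vjps=((x, lambda g: g * factor),))


def mean_abs(x: Tensor) -> Tensor:
    """mean(|x|) with the sign subgradient (0 at 0)."""
    n = x.data.size
    sign = np.sign(x.data)
    return Tensor(
        np.asarray(np.abs(x.data).mean()),
        _vjps=((x, lambda g: g * sign / n),),
    )


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        lo, hi = offsets[i], offsets[i + 1]

        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            return g[tuple(sl)]

        return vjp

    return Tensor(data, _vjps=tuple((t, make_vjp(i)) for i, t in enumerate(tensors)))


def avgpool2(x: Tensor) -> Tensor:
    """Factor-2 average pooling of a (B, C, D, H, W) tensor."""
    b, c, d, h, w = x.data.shape
    if d % 2 or h % 2 or w % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {(d, h, w)}")
    out = x.data.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(3, 5, 7))

    def vjp(g):
        g = g[:, :, :, None, :, None, :, None] / 8.0
        return np.broadcast_to(g, (b, c, d // 2, 2, h // 2, 2, w // 2, 2)).reshape(
            b, c, d, h, w
        )

    return Tensor(out, _vjps=((x, vjp),))


def _up2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    xm = np.moveaxis(x, axis, 0)
    left = np.concatenate([xm[:1], xm[:-1]], axis=0)
    right = np.concatenate([xm[1:], xm[-1:]], axis=0)
    out = np.empty((2 * xm.shape[0],) + xm.shape[1:], dtype=x.dtype)
    out[0::2] = 0.75 * xm + 0.25 * left
    out[1::2] = 0.75 * xm + 0.25 * right
    return np.moveaxis(out, 0, axis)


def _up2_axis_adjoint(dy: np.ndarray, axis: int) -> np.ndarray:
    dm = np.moveaxis(dy, axis, 0)
    de, do = dm[0::2], dm[1::2]
    dx = 0.75 * de + 0.75 * do
    dx[:-1] += 0.25 * de[1:]
    dx[0] += 0.25 * de[0]
    dx[1:] += 0.25 * do[:-1]
    dx[-1] += 0.25 * do[-1]
    return np.moveaxis(dx, 0, axis)


def upsample2_linear(x: Tensor) -> Tensor:
    """Factor-2 trilinear upsampling of the spatial axes of (B, C, D, H, W)."""
    out = x.data
    for ax in (2, 3, 4):
        out = _up2_axis(out, ax)

    def vjp(g):
        for ax in (4, 3, 2):
            g = _up2_axis_adjoint(g, ax)
        return g

    return Tensor(out, _vjps=((x, vjp),))


def upsample2_linear_array(x: np.ndarray) -> np.ndarray:
    """Plain-array version of the factor-2 trilinear upsampling (3D array)."""
    out = x
    for ax in range(x.ndim):
        out = _up2_axis(out, ax)
    return out


def gauss_blur3d(x: Tensor, kernel1d: np.ndarray, spatial_axes=(2, 3, 4)) -> Tensor:
    """Separable zero-padded correlation with a fixed symmetric 1D kernel.

    For a symmetric kernel under zero padding the operator is
    self-adjoint, so the backward pass applies the same blur.
    """

    def blur(a):
        out = a
        for ax in spatial_axes:
            out = ndimage.correlate1d(out, kernel1d, axis=ax, mode="constant", cval=0.0)
        return out

    return Tensor(blur(x.data), _vjps=((x, lambda g: blur(g)),))
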