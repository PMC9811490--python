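"""Volumetric NN layers on the autodiff core.

Tensors are laid out (batch, channels, D, H, W).  Conv3d uses im2col +
matmul with per-sample chunking to bound memory; "same" zero padding
keeps spatial shape.  BatchNorm3d follows the usual convention: biased
batch variance for normalization, unbiased for the running estimate,
running stats blended with momentum.
"""

from __future__ import annotations

import numpy as np

from hemipact.nn.autodiff import Tensor, avgpool2, relu

__all__ = ["Module", "Parameter", "Sequential", "Conv3d", "BatchNorm3d", "AvgPool3d", "ReLU"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module: named parameter/submodule discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, v in self.__dict__.items():
            if isinstance(v, Module):
                yield from v.named_modules(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_modules(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for mname, m in self.named_modules():
            if isinstance(m, BatchNorm3d):
                key = f"{mname}." if mname else ""
                out[f"{key}running_mean"] = m.running_mean.copy()
                out[f"{key}running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name]).astype(p.data.dtype).copy()
        for mname, m in self.named_modules():
            if isinstance(m, BatchNorm3d):
                key = f"{mname}." if mname else ""
                m.running_mean = np.asarray(state[f"{key}running_mean"]).astype(np.float32).copy()
                m.running_var = np.asarray(state[f"{key}running_var"]).astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class AvgPool3d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return avgpool2(x)


class Conv3d(Module):
    """3D convolution, stride 1, "same" zero padding, odd kernel size.

    He-normal initialization from the provided generator keeps builds
    reproducible.
    """

    # patches per chunk are capped so im2col stays within ~64 MB
    _CHUNK_BYTES = 64 * 1024**2

    def __init__(self, c_in: int, c_out: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None, init_std: float | None = None):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel_size**3
        std = np.sqrt(2.0 / fan_in) if init_std is None else init_std
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, kernel_size, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(c_out))
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size

    def _patches(self, xpad: np.ndarray) -> np.ndarray:
        # xpad: (C, D+2p, H+2p, W+2p) -> (D*H*W, C*k^3)
        k = self.k
        v = np.lib.stride_tricks.sliding_window_view(xpad, (k, k, k), axis=(1, 2, 3))
        # v: (C, D, H, W, k, k, k) -> (D, H, W, C, k, k, k)
        v = np.moveaxis(v, 0, 3)
        d, h, w = v.shape[:3]
        return np.ascontiguousarray(v).reshape(d * h * w, self.c_in * k**3)

    def forward(self, x: Tensor) -> Tensor:
        b, c, d, h, w = x.data.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        k, p = self.k, self.k // 2
        wmat = self.weight.data.reshape(self.c_out, -1).T.astype(np.float32)  # (C*k^3, Cout)
        pad = ((0, 0), (0, 0), (p, p), (p, p), (p, p))
        xpad = np.pad(x.data.astype(np.float32, copy=False), pad)
        out = np.empty((b, self.c_out, d, h, w), dtype=np.float32)
        for i in range(b):
            patches = self._patches(xpad[i])
            out[i] = (patches @ wmat).T.reshape(self.c_out, d, h, w)
        out += self.bias.data.reshape(1, -1, 1, 1, 1)

        def vjp_x(g):
            # full correlation of g with the flipped kernel = conv transpose
            gpad = np.pad(g.astype(np.float32, copy=False), pad)
            wt = np.flip(self.weight.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
            wtmat = np.ascontiguousarray(wt).reshape(self.c_in, -1).T.astype(np.float32)
            dx = np.empty((b, self.c_in, d, h, w), dtype=np.float32)
            for i in range(b):
                kk = np.lib.stride_tricks.sliding_window_view(gpad[i], (k, k, k), axis=(1, 2, 3))
                kk = np.moveaxis(kk, 0, 3)
                patches = np.ascontiguousarray(kk).reshape(d * h * w, self.c_out * k**3)
                dx[i] = (patches @ wtmat).T.reshape(self.c_in, d, h, w)
            return dx

        def vjp_w(g):
            dw = np.zeros((self.c_out, self.c_in * k**3), dtype=np.float64)
            for i in range(b):
                patches = self._patches(xpad[i])
                gm = g[i].reshape(self.c_out, -1).astype(np.float32)
                dw += gm @ patches
            return dw.reshape(self.weight.data.shape)

        def vjp_b(g):
            return g.sum(axis=(0, 2, 3, 4))

        return Tensor(out, _vjps=((x, vjp_x), (self.weight, vjp_w), (self.bias, vjp_b)))


class BatchNorm3d(Module):
    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(n_channels))
        self.beta = Parameter(np.zeros(n_channels))
        self.running_mean = np.zeros(n_channels, dtype=np.float32)
        self.running_var = np.ones(n_channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.n_channels = n_channels

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            n = x.data.size // x.data.shape[1]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mu).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * unbiased).astype(np.float32)
        else:
            mu = self.running_mean
            var = self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu.reshape(shape)) * invstd.reshape(shape)
        out = self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

        training = self.training

        def vjp_x(g):
            gsh = self.gamma.data.reshape(shape)
            if not training:
                return g * gsh * invstd.reshape(shape)
            n = x.data.size // x.data.shape[1]
            gxhat = g * gsh
            mean_g = gxhat.mean(axis=axes).reshape(shape)
            mean_gx = (gxhat * xhat).mean(axis=axes).reshape(shape)
            return invstd.reshape(shape) * (gxhat - mean_g - xhat * mean_gx)

        def vjp_gamma(g):
            return (g * xhat).sum(axis=axes)

        def vjp_beta(g):
            return g.sum(axis=axes)

        return Tensor(
            out.astype(np.float32),
            _vjps=((x, vjp_x), (self.gamma, vjp_gamma), (self.beta, vjp_beta)),
        )
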