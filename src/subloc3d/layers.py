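"""Neural-network building blocks on top of :mod:`subloc3d.autodiff`.

Implements the pieces the dual-branch encoder is assembled from: linear
layers, 2-D/3-D ``same``-padded convolutions (kernel 3, arbitrary stride)
via im2col, batch normalisation, residual blocks and the Adam optimiser.

Convolution backward w.r.t. the input is a scatter of the column gradient
back onto the (padded) input grid; we realise it as a cached sparse-matrix
product, which keeps the training loop pure linear algebra.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import sparse

from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv",
    "BatchNorm",
    "ResidualBlock",
    "Adam",
    "global_average_pool",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)
        # parameters stay trainable even if constructed under no_grad
        self.requires_grad = True


class Module:
    """Tiny module base: parameter discovery and train/eval mode."""

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

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def named_parameters(self) -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}

        def visit(mod: Module, prefix: str):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    out[key] = v
                elif isinstance(v, Module):
                    visit(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")
        return out

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                state[f"__bn{i}.mean"] = m.running_mean.copy()
                state[f"__bn{i}.var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.named_parameters().items():
            v.data = state[k].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm):
                m.running_mean = state[f"__bn{i}.mean"].copy()
                m.running_var = state[f"__bn{i}.var"].copy()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_dim))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


# -- convolution -------------------------------------------------------------

_COL2IM_CACHE: dict[tuple, sparse.csc_matrix] = {}


def _conv_geometry(spatial: tuple[int, ...], k: int, stride: int):
    pad = k // 2
    padded = tuple(s + 2 * pad for s in spatial)
    out = tuple((s - 1) // stride + 1 for s in spatial)  # ceil(s / stride)
    return pad, padded, out


def _col2im_matrix(spatial: tuple[int, ...], in_ch: int, k: int,
                   stride: int) -> sparse.csc_matrix:
    """Sparse (P*K, C*prod(padded)) scatter matrix for conv input gradients."""
    key = (spatial, in_ch, k, stride)
    if key in _COL2IM_CACHE:
        return _COL2IM_CACHE[key]
    pad, padded, out = _conv_geometry(spatial, k, stride)
    nd = len(spatial)
    flat = np.arange(in_ch * int(np.prod(padded))).reshape((in_ch,) + padded)
    win = sliding_window_view(flat, (k,) * nd, axis=tuple(range(1, nd + 1)))
    # win shape: (C, *valid_out, *kernel); subsample by stride
    sl = (slice(None),) + tuple(slice(None, None, stride) for _ in range(nd))
    win = win[sl]
    # reorder to (P, C*K) matching the im2col layout used in Conv.__call__
    perm = tuple(range(1, nd + 1)) + (0,) + tuple(range(nd + 1, 2 * nd + 1))
    cols = win.transpose(perm).reshape(-1)
    rows = np.arange(cols.size)
    mat = sparse.csc_matrix(
        (np.ones(cols.size), (rows, cols)),
        shape=(cols.size, in_ch * int(np.prod(padded))),
    )
    _COL2IM_CACHE[key] = mat
    return mat


class Conv(Module):
    """N-dimensional ``same`` convolution (kernel 1 or 3), stride 1 or 2."""

    def __init__(self, nd: int, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel: int = 3, stride: int = 1):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported")
        self.nd, self.in_ch, self.out_ch = nd, in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        fan_in = in_ch * kernel**nd
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        )
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        nd, k, stride = self.nd, self.kernel, self.stride
        B, C = x.shape[0], x.shape[1]
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        spatial = tuple(x.shape[2:])
        pad, padded, out = _conv_geometry(spatial, k, stride)

        pw = ((0, 0), (0, 0)) + ((pad, pad),) * nd
        xp = np.pad(x.data, pw)
        win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, nd + 2)))
        sl = (slice(None), slice(None)) + tuple(
            slice(None, None, stride) for _ in range(nd)
        )
        win = win[sl]
        # (B, C, *out, *kernel) -> (B, P, C*K)
        perm = (0,) + tuple(range(2, nd + 2)) + (1,) + tuple(range(nd + 2, 2 * nd + 2))
        P = int(np.prod(out))
        col = np.ascontiguousarray(win.transpose(perm)).reshape(
            B * P, C * k**nd
        )

        col_t = Tensor._make(
            col, (x,), self._make_input_backward(x, col, B, spatial, padded, pad)
        )
        y = col_t @ self.weight + self.bias  # (B*P, OC) single GEMM
        y = y.reshape(B, P, self.out_ch).transpose(0, 2, 1)
        return y.reshape((B, self.out_ch) + out)

    def _make_input_backward(self, x: Tensor, col: np.ndarray, B: int,
                             spatial: tuple[int, ...], padded: tuple[int, ...],
                             pad: int):
        def backward(gcol: np.ndarray):
            if not x.requires_grad:
                return
            mat = _col2im_matrix(spatial, self.in_ch, self.kernel, self.stride)
            flat = gcol.reshape(B, -1) @ mat  # (B, C*prod(padded))
            gpad = np.asarray(flat).reshape((B, self.in_ch) + padded)
            if pad:
                sl = (slice(None), slice(None)) + tuple(
                    slice(pad, -pad) for _ in spatial
                )
                gpad = gpad[sl]
            x._accumulate(gpad)

        return backward


class BatchNorm(Module):
    """Batch normalisation over (batch, *spatial) per channel."""

    def __init__(self, n_ch: int, nd: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.nd = nd
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)

    def __call__(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, 2 + self.nd))
        shape = (1, -1) + (1,) * self.nd
        if not self.training:
            mu = self.running_mean.reshape(shape)
            sd = np.sqrt(self.running_var + self.eps).reshape(shape)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
            return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)

        # fused training-mode forward/backward (one pass, few temporaries)
        mu = x.data.mean(axis=axes, keepdims=True)
        xc = x.data - mu
        var = np.mean(xc * xc, axis=axes, keepdims=True)
        m = self.momentum
        self.running_mean = (1 - m) * self.running_mean + m * mu.reshape(-1)
        self.running_var = (1 - m) * self.running_var + m * var.reshape(-1)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = xc * inv
        gamma, beta = self.gamma, self.beta
        out_data = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)
        count = x.data.size // x.data.shape[1]

        def backward(g):
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gs = g * gamma.data.reshape(shape)
                mean_gs = gs.mean(axis=axes, keepdims=True)
                mean_gx = np.mean(gs * xhat, axis=axes, keepdims=True)
                x._accumulate(inv * (gs - mean_gs - xhat * mean_gx))
            _ = count  # keep closure size explicit

        return Tensor._make(out_data, (x, gamma, beta), backward)


class ResidualBlock(Module):
    """conv3-BN-ReLU-conv3-BN with a projection skip, ReLU after the sum.

    The first convolution carries the (optional) stride-2 downsampling; the
    skip path uses a 1x1(x1) convolution whenever channels or stride change.
    """

    def __init__(self, nd: int, in_ch: int, out_ch: int, rng: np.random.Generator,
                 stride: int = 1):
        super().__init__()
        self.conv1 = Conv(nd, in_ch, out_ch, rng, kernel=3, stride=stride)
        self.bn1 = BatchNorm(out_ch, nd)
        self.conv2 = Conv(nd, out_ch, out_ch, rng, kernel=3, stride=1)
        self.bn2 = BatchNorm(out_ch, nd)
        self.proj = None
        if in_ch != out_ch or stride != 1:
            self.proj = Conv(nd, in_ch, out_ch, rng, kernel=1, stride=stride)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        skip = x if self.proj is None else self.proj(x)
        return (h + skip).relu()


def global_average_pool(x: Tensor) -> Tensor:
    """(B, C, *spatial) -> (B, C) mean over all spatial axes."""
    axes = tuple(range(2, x.ndim))
    return x.mean(axis=axes)


def global_max_pool(x: Tensor) -> Tensor:
    """(B, C, *spatial) -> (B, C) max over all spatial axes.

    Keeps small high-intensity structures (puncta) visible in the pooled
    feature where averaging would wash them out; gradient routes to the
    argmax voxel.
    """
    B, C = x.shape[0], x.shape[1]
    flat = x.data.reshape(B, C, -1)
    arg = flat.argmax(axis=2)
    out_data = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(flat)
            np.put_along_axis(full, arg[:, :, None], g[:, :, None], axis=2)
            x._accumulate(full.reshape(x.data.shape))

    return Tensor._make(out_data, (x,), backward)


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
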