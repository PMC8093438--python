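"""Minimal 3D neural-network layers with explicit backpropagation.

Everything operates on float32 arrays shaped ``(N, C, D, H, W)`` for spatial
layers and ``(N, F)`` for dense layers.  Convolutions are stride-1 with
'same' zero padding; spatial downsampling is done by 2x2x2 max-pooling.
Each layer caches what its backward pass needs during ``forward`` and writes
parameter gradients into ``self.grads`` during ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3D",
    "GroupedConv3D",
    "SeparableConv3D",
    "BatchNorm",
    "ELU",
    "MaxPool3D",
    "Dropout",
    "Flatten",
    "Dense",
]

DT = np.float32


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(DT)


class Layer:
    """Base: parameter dict, gradient dict, regularizable weight names."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.l2_param_names: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-padded 'same' patches as a (C*k^3, N*V) matrix, V = D*H*W."""
    p = k // 2
    n, c, d, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))  # (N,C,D,H,W,k,k,k)
    return np.ascontiguousarray(win.transpose(1, 5, 6, 7, 0, 2, 3, 4)).reshape(
        c * k**3, n * d * h * wd
    )


def _conv3d_forward(x: np.ndarray, w: np.ndarray, cols: np.ndarray | None = None) -> np.ndarray:
    """Stride-1 'same' cross-correlation via im2col + one GEMM.

    x: (N,C,D,H,W), w: (O,C,k,k,k).  ``cols`` lets the caller reuse the patch
    matrix between forward and backward.
    """
    k = w.shape[2]
    n, c, d, h, wd = x.shape
    o = w.shape[0]
    if cols is None:
        cols = _im2col(x, k)
    out = (w.reshape(o, -1) @ cols).reshape(o, n, d, h, wd)
    return np.ascontiguousarray(out.transpose(1, 0, 2, 3, 4))


def _conv3d_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray, cols: np.ndarray | None = None):
    """Gradients of the stride-1 'same' cross-correlation; returns (dx, dw)."""
    k = w.shape[2]
    p = k // 2
    n, c, d, h, wd = x.shape
    o = w.shape[0]
    if cols is None:
        cols = _im2col(x, k)
    dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3, 4)).reshape(o, -1)  # (O, N*V)
    dw = (dyf @ cols.T).reshape(w.shape)
    dcols = (w.reshape(o, -1).T @ dyf).reshape(c, k, k, k, n, d, h, wd)
    dxp = np.zeros((n, c, d + 2 * p, h + 2 * p, wd + 2 * p), dtype=dy.dtype)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                dxp[:, :, i : i + d, j : j + h, l : l + wd] += dcols[:, i, j, l].transpose(
                    1, 0, 2, 3, 4
                )
    dx = dxp[:, :, p:-p, p:-p, p:-p] if p else dxp
    return np.ascontiguousarray(dx), dw


class Conv3D(Layer):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * kernel**3
        self.params = {
            "w": he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in),
            "b": np.zeros(out_ch, dtype=DT),
        }
        self.l2_param_names = ("w",)

    def forward(self, x, training, rng=None):
        self._x = x
        self._cols = _im2col(x, self.params["w"].shape[2])
        out = _conv3d_forward(x, self.params["w"], cols=self._cols)
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        dx, dw = _conv3d_backward(self._x, self.params["w"], dy, cols=self._cols)
        self.grads = {"w": dw, "b": dy.sum(axis=(0, 2, 3, 4))}
        return dx


class GroupedConv3D(Layer):
    """Grouped convolution: channels split into ``groups`` independent convs."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, groups: int, rng):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("in/out channels must be divisible by groups")
        self.groups = groups
        self.cin_g = in_ch // groups
        self.cout_g = out_ch // groups
        fan_in = self.cin_g * kernel**3
        self.params = {
            "w": he_init(rng, (groups, self.cout_g, self.cin_g, kernel, kernel, kernel), fan_in),
            "b": np.zeros(out_ch, dtype=DT),
        }
        self.l2_param_names = ("w",)

    def forward(self, x, training, rng=None):
        self._x = x
        outs = []
        for g in range(self.groups):
            xg = x[:, g * self.cin_g : (g + 1) * self.cin_g]
            outs.append(_conv3d_forward(xg, self.params["w"][g]))
        out = np.concatenate(outs, axis=1)
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        dxs = []
        dw = np.empty_like(self.params["w"])
        for g in range(self.groups):
            xg = self._x[:, g * self.cin_g : (g + 1) * self.cin_g]
            dyg = dy[:, g * self.cout_g : (g + 1) * self.cout_g]
            dxg, dwg = _conv3d_backward(xg, self.params["w"][g], dyg)
            dxs.append(dxg)
            dw[g] = dwg
        self.grads = {"w": dw, "b": dy.sum(axis=(0, 2, 3, 4))}
        return np.concatenate(dxs, axis=1)


class SeparableConv3D(Layer):
    """Depthwise spatial convolution followed by a 1x1x1 pointwise mix."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng):
        super().__init__()
        self.in_ch = in_ch
        self.params = {
            # one k^3 filter per input channel
            "dw": he_init(rng, (in_ch, 1, kernel, kernel, kernel), kernel**3),
            "pw": he_init(rng, (out_ch, in_ch), in_ch),
            "b": np.zeros(out_ch, dtype=DT),
        }
        self.l2_param_names = ("dw", "pw")

    def forward(self, x, training, rng=None):
        self._x = x
        k = self.params["dw"].shape[2]
        p = k // 2
        n, c, d, h, wd = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        self._xp = xp
        mid = np.zeros_like(x)
        wdw = self.params["dw"][:, 0]  # (C,k,k,k)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    mid += wdw[:, i, j, l][None, :, None, None, None] * xp[
                        :, :, i : i + d, j : j + h, l : l + wd
                    ]
        self._mid = mid
        midf = mid.reshape(n, c, -1)
        out = (self.params["pw"] @ midf).reshape(n, -1, d, h, wd)
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, dy):
        n, o = dy.shape[:2]
        d, h, wd = dy.shape[2:]
        c = self.in_ch
        dyf = dy.reshape(n, o, -1)
        midf = self._mid.reshape(n, c, -1)
        dpw = np.tensordot(dyf, midf, axes=([0, 2], [0, 2]))  # (O, C)
        dmid = (self.params["pw"].T @ dyf).reshape(n, c, d, h, wd)
        k = self.params["dw"].shape[2]
        p = k // 2
        xp = self._xp
        dxp = np.zeros_like(xp)
        ddw = np.empty_like(self.params["dw"])
        wdw = self.params["dw"][:, 0]
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, :, i : i + d, j : j + h, l : l + wd]
                    ddw[:, 0, i, j, l] = (dmid * xs).sum(axis=(0, 2, 3, 4))
                    dxp[:, :, i : i + d, j : j + h, l : l + wd] += (
                        wdw[:, i, j, l][None, :, None, None, None] * dmid
                    )
        dx = dxp[:, :, p:-p, p:-p, p:-p] if p else dxp
        self.grads = {"dw": ddw, "pw": dpw, "b": dy.sum(axis=(0, 2, 3, 4))}
        return np.ascontiguousarray(dx)


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel/feature axis.

    ``spatial=True`` normalizes (N, C, D, H, W) per channel; ``spatial=False``
    normalizes (N, F) per feature.  Running statistics (momentum 0.9) are used
    in evaluation mode.
    """

    def __init__(self, n_ch: int, spatial: bool = True, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.spatial = spatial
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(n_ch, dtype=DT), "beta": np.zeros(n_ch, dtype=DT)}
        self.running_mean = np.zeros(n_ch, dtype=DT)
        self.running_var = np.ones(n_ch, dtype=DT)

    def _bshape(self):
        return (1, -1, 1, 1, 1) if self.spatial else (1, -1)

    def _axes(self):
        return (0, 2, 3, 4) if self.spatial else (0,)

    def forward(self, x, training, rng=None):
        bs = self._bshape()
        if training:
            mu = x.mean(axis=self._axes())
            var = x.var(axis=self._axes())
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mu).astype(DT)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(DT)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu.reshape(bs)) * inv.reshape(bs)
        self._cache = (xhat, inv, training)
        return self.params["gamma"].reshape(bs) * xhat + self.params["beta"].reshape(bs)

    def backward(self, dy):
        xhat, inv, training = self._cache
        bs = self._bshape()
        axes = self._axes()
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        g = self.params["gamma"].reshape(bs) * inv.reshape(bs)
        if not training:
            return dy * g  # running stats are constants w.r.t. the input
        m = dy.size // dy.shape[1]
        return (g / m) * (m * dy - dbeta.reshape(bs) - xhat * dgamma.reshape(bs))


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training, rng=None):
        out = np.where(x > 0, x, self.alpha * np.expm1(x)).astype(x.dtype)
        self._cache = (x > 0, out)
        return out

    def backward(self, dy):
        pos, out = self._cache
        return dy * np.where(pos, 1.0, out + self.alpha).astype(dy.dtype)


class MaxPool3D(Layer):
    """2x2x2 max pooling, stride 2; odd trailing voxels are cropped."""

    def forward(self, x, training, rng=None):
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xc = x[:, :, : 2 * d2, : 2 * h2, : 2 * w2]
        win = xc.reshape(n, c, d2, 2, h2, 2, w2, 2).transpose(0, 1, 2, 4, 6, 3, 5, 7)
        win = win.reshape(n, c, d2, h2, w2, 8)
        self._idx = win.argmax(axis=-1)
        self._in_shape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = dy.shape[2:]
        dwin = np.zeros(dy.shape + (8,), dtype=dy.dtype)
        np.put_along_axis(dwin, self._idx[..., None], dy[..., None], axis=-1)
        dwin = dwin.reshape(n, c, d2, h2, w2, 2, 2, 2).transpose(0, 1, 2, 5, 3, 6, 4, 7)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :, : 2 * d2, : 2 * h2, : 2 * w2] = dwin.reshape(n, c, 2 * d2, 2 * h2, 2 * w2)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode or at rate 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng):
        super().__init__()
        self.params = {"w": he_init(rng, (in_f, out_f), in_f), "b": np.zeros(out_f, dtype=DT)}
        self.l2_param_names = ("w",)

    def forward(self, x, training, rng=None):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dy):
        self.grads = {"w": self._x.T @ dy, "b": dy.sum(axis=0)}
        return dy @ self.params["w"].T
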