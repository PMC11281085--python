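"""Layers with explicit forward/backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    """Base layer: parameters and their gradients live in two dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_items(self):
        for key in self.params:
            yield self, key

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _pad2d(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))


class Conv2D(Layer):
    """Standard k x k convolution (no bias; batch norm follows).

    k == 1 is the pointwise convolution fast path (a channel-mixing
    matmul); k > 1 uses im2col.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        rng = rng or np.random.default_rng(0)
        self.params["w"] = he_uniform(rng, (cout, cin * k * k), fan_in=cin * k * k)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.k == 1:
            self._x = x
            w = self.params["w"]  # (cout, cin)
            y = np.tensordot(w, x, axes=([1], [1]))  # (cout, N, H, W)
            return np.ascontiguousarray(y.transpose(1, 0, 2, 3))
        xp = _pad2d(x, self.pad)
        n, c, h, w = xp.shape
        oh = (h - self.k) // self.stride + 1
        ow = (w - self.k) // self.stride + 1
        s0, s1, s2, s3 = xp.strides
        win = np.lib.stride_tricks.as_strided(
            xp, (n, c, self.k, self.k, oh, ow),
            (s0, s1, s2, s3, s2 * self.stride, s3 * self.stride),
        )
        cols = np.ascontiguousarray(win).reshape(n, c * self.k * self.k, oh * ow)
        self._cols, self._xshape = cols, x.shape
        y = np.matmul(self.params["w"], cols)  # (n, cout, oh*ow)
        return y.reshape(n, self.cout, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.k == 1:
            x = self._x
            w = self.params["w"]
            self.grads["w"] = np.einsum("nohw,nchw->oc", dout, x, optimize=True)
            dx = np.tensordot(w.T, dout, axes=([1], [1])).transpose(1, 0, 2, 3)
            return np.ascontiguousarray(dx)
        n, cout, oh, ow = dout.shape
        dflat = dout.reshape(n, cout, oh * ow)
        self.grads["w"] = np.einsum("nol,nkl->ok", dflat, self._cols, optimize=True)
        dcols = np.matmul(self.params["w"].T, dflat)  # (n, cin*k*k, oh*ow)
        dcols = dcols.reshape(n, self.cin, self.k, self.k, oh, ow)
        _, _, h, w = self._xshape
        hp, wp = h + 2 * self.pad, w + 2 * self.pad
        dxp = np.zeros((n, self.cin, hp, wp), dtype=dout.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += dcols[:, :, i, j]
        p = self.pad
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class DepthwiseConv2D(Layer):
    """Per-channel k x k convolution (no bias), via k^2 shifted slices."""

    def __init__(self, channels: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.c, self.k, self.stride = channels, k, stride
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        self.params["w"] = he_uniform(rng, (channels, k, k), fan_in=k * k)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xp = _pad2d(x, self.pad)
        n, c, h, w = xp.shape
        oh = (h - self.k) // self.stride + 1
        ow = (w - self.k) // self.stride + 1
        self._xp, self._xshape = xp, x.shape
        wgt = self.params["w"]
        y = np.zeros((n, c, oh, ow), dtype=np.result_type(xp, wgt))
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                y += wgt[:, i, j][None, :, None, None] * xp[
                    :, :, i : i + s * oh : s, j : j + s * ow : s
                ]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, oh, ow = dout.shape
        s = self.stride
        wgt = self.params["w"]
        dw = np.zeros_like(wgt)
        dxp = np.zeros_like(self._xp)
        for i in range(self.k):
            for j in range(self.k):
                sl = self._xp[:, :, i : i + s * oh : s, j : j + s * ow : s]
                dw[:, i, j] = np.einsum("nchw,nchw->c", dout, sl, optimize=True)
                dxp[:, :, i : i + s * oh : s, j : j + s * ow : s] += (
                    wgt[:, i, j][None, :, None, None] * dout
                )
        self.grads["w"] = dw
        p = self.pad
        _, _, h, w = self._xshape
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2D(Layer):
    """Per-channel batch normalisation with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._xhat, self._inv, self._training = xhat, inv, training
        g, b = self.params["gamma"], self.params["beta"]
        return g[None, :, None, None] * self._xhat + b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3)
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"] = np.einsum("nchw,nchw->c", dout, xhat, optimize=True)
        self.grads["beta"] = dout.sum(axis=axes)
        g = self.params["gamma"]
        if not self._training:
            return dout * (g * inv)[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dmean = dout.mean(axis=axes)
        dxhat_mean = (dout * xhat).sum(axis=axes) / m
        dx = (g * inv)[None, :, None, None] * (
            dout - dmean[None, :, None, None] - xhat * dxhat_mean[None, :, None, None]
        )
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        # clip keeps exp() in range; sigmoid saturates well before |x| = 60
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return (
            np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)
        )


class Dense(Layer):
    """Affine map y = x W + b on (N, din) inputs."""

    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = he_uniform(rng, (din, dout), fan_in=din)
        self.params["b"] = np.zeros(dout, dtype=DTYPE)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class Sequential(Layer):
    """A chain of layers applied in order."""

    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def param_items(self):
        for layer in self.layers:
            yield from layer.param_items()

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)
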