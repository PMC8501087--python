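"""Minimal numpy layers with hand-written backprop.

Only what the segmentation network needs: 3x3/1x1 convolutions, batch
normalization, ReLU, 2x2 max pooling, x2 bilinear upsampling, channel
concatenation and softmax. Each layer caches its forward intermediates and
accumulates parameter gradients into preallocated arrays (``gw``/``gb``) so
optimizers can hold stable references.

Everything runs in float32 by default; float64 is supported for numerical
gradient checks.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def params(self):
        """List of (weight, gradient) array pairs updated in place."""
        return []

    def buffers(self):
        """Non-trainable state (e.g. BN running statistics)."""
        return []


class Conv2d(Layer):
    """Same-padding convolution, kernel size 1 or 3, via im2col."""

    def __init__(self, cin: int, cout: int, ksize: int,
                 rng: np.random.Generator, dtype=np.float32):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.cin, self.cout, self.k = cin, cout, ksize
        fan_in = cin * ksize * ksize
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        self.w = rng.normal(0.0, std, size=(fan_in, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        if self.k == 1:
            cols = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, C)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                        ).reshape(B * H * W, C * 9)
        out = cols @ self.w + self.b
        self._cache = (cols, (B, C, H, W))
        return out.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W) = self._cache
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.gw[...] = cols.T @ dmat
        self.gb[...] = dmat.sum(axis=0)
        dcols = dmat @ self.w.T
        if self.k == 1:
            return dcols.reshape(B, H, W, C).transpose(0, 3, 1, 2)
        dcols = dcols.reshape(B, H, W, C, 3, 3)
        dxp = np.zeros((B, C, H + 2, W + 2), dtype=dout.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + H, j:j + W] += dcols[:, :, :, :, i, j
                                                     ].transpose(0, 3, 1, 2)
        return dxp[:, :, 1:H + 1, 1:W + 1]


class BatchNorm2d(Layer):
    """Per-channel batch normalization; batch statistics in training mode,
    running averages in evaluation mode. Batch size >= 2 enforced during
    training (BN is degenerate at size 1)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self._cache = None

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            if x.shape[0] < 2:
                raise ValueError("BatchNorm requires batch size >= 2 in "
                                 "training mode")
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean[...] = ((1 - self.momentum) * self.running_mean
                                      + self.momentum * mean)
            self.running_var[...] = ((1 - self.momentum) * self.running_var
                                     + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std) if train else None
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.ggamma[...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; first-maximum tie-break."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
        idx = flat.argmax(axis=-1)
        self._cache = (idx, (B, C, H, W))
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W) = self._cache
        dflat = np.zeros((B, C, H // 2, W // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx).reshape(B, C, H, W)


def _up_matrix(n: int, dtype) -> np.ndarray:
    """(2n, n) bilinear interpolation matrix (half-pixel centre alignment)."""
    a = np.zeros((2 * n, n), dtype=dtype)
    for i in range(2 * n):
        src = (i + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(src))
        t = src - i0
        a[i, min(max(i0, 0), n - 1)] += 1.0 - t
        a[i, min(max(i0 + 1, 0), n - 1)] += t
    return a


class BilinearUp2(Layer):
    """x2 bilinear upsampling as a separable linear map (exact transpose in
    backward)."""

    _matrices: dict = {}

    def _mat(self, n: int, dtype) -> np.ndarray:
        key = (n, np.dtype(dtype).str)
        if key not in BilinearUp2._matrices:
            BilinearUp2._matrices[key] = _up_matrix(n, dtype)
        return BilinearUp2._matrices[key]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, H, W = x.shape
        ah, aw = self._mat(H, x.dtype), self._mat(W, x.dtype)
        self._cache = (ah, aw)
        y = np.einsum("ph,bchw->bcpw", ah, x, optimize=True)
        return np.einsum("qw,bcpw->bcpq", aw, y, optimize=True)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        ah, aw = self._cache
        d = np.einsum("qw,bcpq->bcpw", aw, dout, optimize=True)
        return np.einsum("ph,bcpw->bchw", ah, d, optimize=True)


class Softmax(Layer):
    """Channel-axis softmax; backward consumes dL/dp directly."""

    def forward(self, z: np.ndarray, train: bool) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        self._p = p
        return p

    def backward(self, dldp: np.ndarray) -> np.ndarray:
        p = self._p
        inner = (dldp * p).sum(axis=1, keepdims=True)
        return p * (dldp - inner)
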