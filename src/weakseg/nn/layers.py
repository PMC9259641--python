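"""Minimal NCHW conv-net layers with explicit backprop, built on BLAS matmul.

Only what the segmentation U-net needs: 3x3 'same' convolution (im2col),
1x1 convolution, ReLU, 2x2 max-pooling, nearest-neighbour 2x upsampling,
channel concatenation and a per-pixel softmax.  Arrays are float64
(N, C, H, W); parameters live in ``Conv2D`` objects, updated by an external
SGDM optimiser.
"""

from __future__ import annotations

import numpy as np


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches of the zero-padded 3x3 windows."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c * 9, h * w), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, k * c : (k + 1) * c, :] = xp[:, :, dy : dy + h, dx : dx + w].reshape(n, c, h * w)
            k += 1
    return cols


def _col2im3(dcols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of ``_im2col3``: scatter-add patch gradients back to the image."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            dxp[:, :, dy : dy + h, dx : dx + w] += dcols[:, k * c : (k + 1) * c, :].reshape(n, c, h, w)
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


class Conv2D:
    """3x3 (or 1x1) same-padding convolution with bias."""

    def __init__(self, rng: np.random.Generator, in_ch: int, out_ch: int, kernel: int = 3):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch * kernel * kernel
        self.w = he_init(rng, fan_in, (out_ch, fan_in))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        # SGDM state
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if self.kernel == 1:
            cols = x.reshape(n, c, h * w)
        else:
            cols = _im2col3(x)
        y = np.matmul(self.w, cols) + self.b[None, :, None]
        self._cache = (cols, x.shape)
        return y.reshape(n, self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        dyf = dy.reshape(n, self.out_ch, h * w)
        self.dw = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.db = dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, dyf)
        if self.kernel == 1:
            return dcols.reshape(xshape)
        return _col2im3(dcols, xshape)

    @property
    def params(self):
        return [(self.w, self.dw, self.vw), (self.b, self.db, self.vb)]


class BatchNorm2D:
    """Per-channel batch normalisation with running statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.vgamma = np.zeros(channels)
        self.vbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv_std[None, :, None, None]
        dy_sum = dy.sum(axis=(0, 2, 3))[None, :, None, None]
        dyx_sum = (dy * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return g * (dy - dy_sum / m - xhat * dyx_sum / m)

    @property
    def params(self):
        return [(self.gamma, self.dgamma, self.vgamma), (self.beta, self.dbeta, self.vbeta)]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2x2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        self._idx = idx
        self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2x:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax_channels(z: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of (N, K, H, W) logits."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of the channel softmax: dL/dz from dL/dp."""
    dot = (dp * p).sum(axis=1, keepdims=True)
    return p * (dp - dot)
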