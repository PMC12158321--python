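"""Minimal NumPy layers with explicit forward/backward passes.

Only what the segmentation network needs: 2-D convolution (arbitrary odd or
even kernel, stride, reflect or zero padding), ReLU, 2x2 max pooling and
nearest-neighbour x2 upsampling.  Convolutions are evaluated by summing k*k
strided slices (an unrolled im2col), which keeps memory flat and is fast
enough for the small networks trained here.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidArgumentError

__all__ = ["Conv2d", "ReLU", "MaxPool2", "NearestUpsample2"]


def _reflect_pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")


def _reflect_unpad_grad(g: np.ndarray, p: int) -> np.ndarray:
    """Fold the gradient of a reflect-padded tensor back onto the interior."""
    if p == 0:
        return g
    a = g.copy()
    hp = a.shape[2]
    for i in range(p):                      # rows: padded i mirrors interior 2p - i
        a[:, :, 2 * p - i, :] += a[:, :, i, :]
        a[:, :, hp - 1 - 2 * p + i, :] += a[:, :, hp - 1 - i, :]
    wp = a.shape[3]
    for j in range(p):
        a[:, :, :, 2 * p - j] += a[:, :, :, j]
        a[:, :, :, wp - 1 - 2 * p + j] += a[:, :, :, wp - 1 - j]
    return a[:, :, p:-p, p:-p]


class Conv2d:
    """2-D convolution with bias.  Input/output layout: (N, C, H, W)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        pad_mode: str = "reflect",
        rng: np.random.Generator | None = None,
    ) -> None:
        if pad_mode not in ("reflect", "zeros"):
            raise InvalidArgumentError(f"unknown pad mode {pad_mode!r}")
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        # He initialisation, appropriate for the ReLU ladders used here
        std = np.sqrt(2.0 / (in_channels * kernel_size * kernel_size))
        self.weight = rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        self.bias = np.zeros(out_channels)
        self._cache: tuple | None = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.weight, self.bias]

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if self.pad_mode == "reflect":
            xp = _reflect_pad(x, p)
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        n, c, hp, wp = xp.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        out = np.zeros((n, self.out_channels, ho, wo))
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                # (N,C,Ho,Wo) x (O,C) -> (N,O,Ho,Wo)
                out += np.einsum("nchw,oc->nohw", patch, self.weight[:, :, ki, kj], optimize=True)
        out += self.bias[None, :, None, None]
        if train:
            self._cache = (xp, x.shape)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise InvalidArgumentError("backward called before a training forward pass")
        xp, x_shape = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        n, c, hp, wp = xp.shape
        ho, wo = g.shape[2], g.shape[3]
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = g.sum(axis=(0, 2, 3))
        gxp = np.zeros_like(xp)
        for ki in range(k):
            for kj in range(k):
                patch = xp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s]
                self.grad_weight[:, :, ki, kj] = np.einsum("nohw,nchw->oc", g, patch, optimize=True)
                gxp[:, :, ki:ki + s * ho:s, kj:kj + s * wo:s] += np.einsum(
                    "nohw,oc->nchw", g, self.weight[:, :, ki, kj], optimize=True
                )
        if p == 0:
            gx = gxp
        elif self.pad_mode == "reflect":
            gx = _reflect_unpad_grad(gxp, p)
        else:
            gx = gxp[:, :, p:-p, p:-p]
        self._cache = None
        return gx


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2 (the baseline subsampling block)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise InvalidArgumentError("max pooling needs even spatial size")
        blocks = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = blocks.max(axis=(3, 5))
        if train:
            self._argmask = blocks == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        spread = self._argmask * g[:, :, :, None, :, None]
        return spread.reshape(n, c, h, w)


class NearestUpsample2:
    """Nearest-neighbour x2 upsampling (hole-free, no learned parameters)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = g.shape
        return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
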