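"""Minimal 3D convolutional layers with hand-written backpropagation.

Everything operates on single volumes laid out channel-first, shape
(C, D, H, W), in float32.  Convolutions are 3x3x3, zero-padded to preserve
shape.  They are realized by stacking the 27 shifted views of the padded
input into a (C*27, N) matrix and issuing one GEMM against the flattened
filter bank; the input-gradient pass reuses the same primitive with a
spatially flipped, transposed filter bank, and the weight gradient is a
single GEMM against the cached stack.

This module exists because the surrounding pipeline is NumPy/SciPy native
and the networks involved are small; it is not a general deep-learning
framework.  Layers expose ``forward(x, cache=...)``/``backward``; parameters
are plain arrays mutated in place by :class:`Adam`.
"""

from __future__ import annotations

import ctypes

import numpy as np


def _tune_malloc() -> None:
    """Keep large freed buffers on the malloc heap for reuse.

    Training allocates and releases multi-hundred-MB shift stacks every
    step; with glibc's default mmap threshold each round trip returns the
    pages to the kernel and re-faults them on next touch, which dominates
    runtime on virtualized hosts.  Raising the mmap/trim thresholds makes
    those buffers heap-recycled.  No-op on non-glibc platforms.
    """
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 30)  # M_TRIM_THRESHOLD
    except (OSError, AttributeError):
        pass


_tune_malloc()

__all__ = [
    "Conv3d",
    "ReLU",
    "MaxPool2x",
    "MeanPool2x",
    "UpsampleNearest2x",
    "Adam",
]

_F32 = np.float32


def _shift_stack(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (C*27, D*H*W) matrix of the 27 zero-padded shifts.

    Row c*27 + (di*9 + dj*3 + dk) holds the input shifted by offset
    (di-1, dj-1, dk-1), matching the flattening order of a (C, 3, 3, 3)
    filter block.
    """
    c, d, h, w = x.shape
    n = d * h * w
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.empty((c, 27, n), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            for dk in range(3):
                o = di * 9 + dj * 3 + dk
                np.copyto(
                    out[:, o, :].reshape(c, d, h, w),
                    xp[:, di : di + d, dj : dj + h, dk : dk + w],
                )
    return out.reshape(c * 27, n)


def _conv3d(x: np.ndarray, weight: np.ndarray, stack: np.ndarray | None = None) -> np.ndarray:
    """Same-size 3x3x3 cross-correlation. x: (C,D,H,W), weight: (O,C,3,3,3)."""
    _, d, h, w = x.shape
    if stack is None:
        stack = _shift_stack(x)
    out = weight.reshape(weight.shape[0], -1) @ stack  # (O, N)
    return out.reshape(weight.shape[0], d, h, w)


class Conv3d:
    """3x3x3 convolution, zero-padded.  He-uniform init.

    With ``cache=True`` the forward pass keeps the shift stack for the
    weight-gradient GEMM in :meth:`backward`; inference passes skip it.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (cin * 27))
        self.W = rng.uniform(-bound, bound, size=(cout, cin, 3, 3, 3)).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._stack: np.ndarray | None = None
        self._shape: tuple | None = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        stack = _shift_stack(x)
        self._stack = stack if cache else None
        self._shape = x.shape
        out = _conv3d(x, self.W, stack=stack)
        return out + self.b[:, None, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._stack is None:
            raise RuntimeError("backward called without a cached forward pass")
        cout = self.W.shape[0]
        gm = g.reshape(cout, -1)
        self.gW += (gm @ self._stack.T).reshape(self.W.shape)
        self.gb += gm.sum(axis=1)
        self._stack = None  # free eagerly; large at full resolution
        w_t = np.ascontiguousarray(np.flip(self.W, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4))
        return _conv3d(g, w_t)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class ReLU:
    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        mask = x > 0
        if cache:
            self._mask = mask
        return np.where(mask, x, _F32(0))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, _F32(0))

    def params(self):
        return []


class MaxPool2x:
    """2x2x2 max pooling; even spatial dims required.  First-occurrence
    tie-break so the backward pass routes each gradient to one voxel."""

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {x.shape}")
        xr = (
            x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 5, 2, 4, 6)
            .reshape(c, d // 2, h // 2, w // 2, 8)
        )
        idx = xr.argmax(axis=-1)
        if cache:
            self._idx = idx
            self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        gz = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=g.dtype)
        np.put_along_axis(gz, self._idx[..., None], g[..., None], axis=-1)
        return (
            gz.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, d, h, w)
        )

    def params(self):
        return []


class MeanPool2x:
    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {x.shape}")
        self._shape = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6)).astype(x.dtype)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = self._shape
        g8 = (g / 8.0).astype(g.dtype)
        out = np.broadcast_to(
            g8[:, :, None, :, None, :, None], (c, d // 2, 2, h // 2, 2, w // 2, 2)
        )
        return np.ascontiguousarray(out).reshape(c, d, h, w)

    def params(self):
        return []


class UpsampleNearest2x:
    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c, d, h, w = g.shape
        return g.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6)).astype(g.dtype)

    def params(self):
        return []


class Adam:
    """Adaptive-moment optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / bc1
            vh = self.v[i] / bc2
            p -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0
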