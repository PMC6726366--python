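"""Minimal CNN building blocks on NumPy arrays (NHWC layout).

Convolutions are lowered to one BLAS GEMM per layer per batch via an
im2col buffer filled by a compiled span-copy kernel; the backward pass
reuses the same buffer for the weight gradient and scatters the input
gradient back with the adjoint kernel.  Layouts and GEMM orientations
were chosen so every matrix product has many rows (pixels) and few
columns (channels), the shape single-threaded BLAS handles well.

Every layer caches what its backward pass needs from the most recent
forward call; the attribution code reuses the same caches to run
modified backward rules (guided ReLU gating, z⁺/z^B relevance).
"""

from __future__ import annotations

from typing import Iterable

import numba
import numpy as np
from scipy import fft as _sfft

__all__ = [
    "Layer", "Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "Dropout",
    "he_normal", "softmax", "weighted_cross_entropy", "MomentumSGD",
]


@numba.njit(cache=True)
def _im2col(xp2, cols, H, W, k, C):  # pragma: no cover - compiled
    # xp2: (N, H+k-1, (W+k-1)*C) flattened padded input
    # cols: (N, H, W, k, k*C) output buffer; innermost copy is one
    # contiguous span of k*C floats per (row offset).
    N = xp2.shape[0]
    for n in range(N):
        for h in range(H):
            for ki in range(k):
                for w in range(W):
                    cols[n, h, w, ki, :] = xp2[n, h + ki, w * C:(w + k) * C]


@numba.njit(cache=True)
def _col2im(dcols, dxp2, H, W, k, C):  # pragma: no cover - compiled
    N = dxp2.shape[0]
    for n in range(N):
        for h in range(H):
            for ki in range(k):
                for w in range(W):
                    dxp2[n, h + ki, w * C:(w + k) * C] += dcols[n, h, w, ki, :]


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
              dtype=np.float32) -> np.ndarray:
    """He initialization: Normal(0, sqrt(2 / fan_in))."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Layer:
    """Base layer: parameters in ``params``, gradients in ``grads``."""

    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def init(self, rng: np.random.Generator, dtype=np.float32) -> None:
        pass

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def astype(self, dtype) -> "Layer":
        for k in self.params:
            self.params[k] = self.params[k].astype(dtype)
        return self


class Conv2D(Layer):
    """Same-padded stride-1 convolution.

    The kernel is stored as a (k·k·C_in, C_out) matrix whose row order
    matches the im2col buffer: row index = (ki·k + kj)·C_in + c.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, name: str = "conv"):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, ksize
        self.name = name

    def init(self, rng, dtype=np.float32):
        fan_in = self.k * self.k * self.in_ch
        self.params["W"] = he_normal(rng, (fan_in, self.out_ch), fan_in, dtype)
        self.params["b"] = np.zeros(self.out_ch, dtype)

    # -- im2col plumbing shared with the attribution rules ---------------
    def _cols(self, x: np.ndarray) -> np.ndarray:
        n, H, W, C = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        xp2 = np.ascontiguousarray(xp).reshape(n, H + 2 * p, (W + 2 * p) * C)
        cols = np.empty((n, H, W, k, k * C), x.dtype)
        _im2col(xp2, cols, H, W, k, C)
        return cols.reshape(n, H * W, k * k * C)

    def _uncols(self, dcols: np.ndarray, xshape: tuple[int, ...]) -> np.ndarray:
        n, H, W, C = xshape
        k, p = self.k, self.k // 2
        dxp2 = np.zeros((n, H + 2 * p, (W + 2 * p) * C), dcols.dtype)
        _col2im(dcols.reshape(n, H, W, k, k * C), dxp2, H, W, k, C)
        dxp = dxp2.reshape(n, H + 2 * p, W + 2 * p, C)
        return dxp[:, p:p + H, p:p + W]

    def conv_with(self, x: np.ndarray, Wmat: np.ndarray) -> np.ndarray:
        """Convolve ``x`` with an arbitrary kernel matrix, no bias."""
        n, H, W, _ = x.shape
        return np.matmul(self._cols(x), Wmat).reshape(n, H, W, -1)

    def input_grad_with(self, dout: np.ndarray, Wmat: np.ndarray,
                        xshape: tuple[int, ...]) -> np.ndarray:
        """Adjoint (transposed) convolution of ``dout`` with ``Wmat``."""
        n, H, W, C = xshape
        dcols = np.matmul(dout.reshape(n, H * W, -1), Wmat.T)
        return self._uncols(dcols, xshape)

    # -- FFT path: correlation via frequency-domain channel GEMMs ---------
    # For 5x5 kernels on large feature maps this avoids both the k^2-fold
    # im2col copy and the worst BLAS GEMM shapes; it computes the exact
    # same same-padded correlation (up to float rounding).
    def _use_fft(self, H: int) -> bool:
        return (self.k == 5 and H >= 16) or (self.k == 3 and H >= 32)

    def _fft_forward(self, x: np.ndarray) -> np.ndarray:
        n, H, W, C = x.shape
        k, p = self.k, self.k // 2
        S = _sfft.next_fast_len(max(H, W) + k - 1, real=True)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        Xf = _sfft.rfft2(xp, s=(S, S), axes=(1, 2))              # (n,S,Sr,C)
        Wk = self.params["W"].reshape(k, k, C, self.out_ch)
        Wf = _sfft.rfft2(Wk, s=(S, S), axes=(0, 1))              # (S,Sr,C,Co)
        Yf = np.matmul(Xf.transpose(1, 2, 0, 3), np.conj(Wf))
        y = _sfft.irfft2(Yf.transpose(2, 0, 1, 3), s=(S, S), axes=(1, 2))
        self._Xf, self._Wf, self._fft_S = Xf, Wf, S
        out = np.ascontiguousarray(y[:, :H, :W, :], dtype=x.dtype)
        out += self.params["b"].astype(x.dtype)
        return out

    def _fft_backward(self, dout: np.ndarray):
        n, H, W, C = self._xshape
        k, p, S = self.k, self.k // 2, self._fft_S
        do = dout.reshape(n, H, W, self.out_ch)
        dYf = _sfft.rfft2(do, s=(S, S), axes=(1, 2))
        prod = np.matmul(self._Xf.transpose(1, 2, 3, 0),
                         np.conj(dYf).transpose(1, 2, 0, 3))
        dWk = _sfft.irfft2(prod, s=(S, S), axes=(0, 1))[:k, :k]
        dXf = np.matmul(dYf.transpose(1, 2, 0, 3),
                        self._Wf.transpose(0, 1, 3, 2))
        dxp = _sfft.irfft2(dXf.transpose(2, 0, 1, 3), s=(S, S), axes=(1, 2))
        dW = dWk.reshape(k * k * C, self.out_ch).astype(dout.dtype)
        dx = np.ascontiguousarray(dxp[:, p:p + H, p:p + W, :], dtype=dout.dtype)
        return dW, dx

    # -- training path ----------------------------------------------------
    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        self._x = x
        n, H, W, _ = x.shape
        if self._use_fft(H):
            self._cols_cache = None
            return self._fft_forward(x)
        self._cols_cache = self._cols(x)
        out = np.matmul(self._cols_cache, self.params["W"])
        out += self.params["b"]
        return out.reshape(n, H, W, self.out_ch)

    def backward(self, dout):
        n, H, W, C = self._xshape
        do = dout.reshape(n, H * W, self.out_ch)
        self.grads["b"] = do.sum(axis=(0, 1))
        if self._cols_cache is None:
            self.grads["W"], dx = self._fft_backward(dout)
            return dx
        cols = self._cols_cache
        self.grads["W"] = np.matmul(cols.transpose(0, 2, 1), do).sum(axis=0)
        dcols = np.matmul(do, self.params["W"].T)
        return self._uncols(dcols, self._xshape)


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__()
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout, guided: bool = False):
        if guided:
            return dout * (self._mask & (dout > 0))
        return dout * self._mask


class MaxPool2(Layer):
    """2×2 max pooling with stride 2; ties route to the first element
    in row-major window order (used both for the gradient and for
    winner-take-all relevance routing)."""

    def __init__(self, name: str = "pool"):
        super().__init__()
        self.name = name

    def forward(self, x, train=False, rng=None):
        n, H, W, C = x.shape
        self._xshape = x.shape
        win = x.reshape(n, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, H // 2, W // 2, C, 4)
        self._idx = win.argmax(axis=-1)
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        return self.route(dout)

    def route(self, values: np.ndarray) -> np.ndarray:
        """Scatter pooled-grid values back to their argmax positions."""
        n, H, W, C = self._xshape
        win = np.zeros((n, H // 2, W // 2, C, 4), values.dtype)
        np.put_along_axis(win, self._idx[..., None], values[..., None], axis=-1)
        win = win.reshape(n, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return win.reshape(n, H, W, C)


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__()
        self.name = name

    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, name: str = "fc"):
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.name = name

    def init(self, rng, dtype=np.float32):
        self.params["W"] = he_normal(rng, (self.in_dim, self.out_dim), self.in_dim, dtype)
        self.params["b"] = np.zeros(self.out_dim, dtype)

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True`` and an rng is
    supplied, so inference is deterministic."""

    def __init__(self, rate: float, name: str = "dropout"):
        super().__init__()
        self.rate = float(rate)
        self.name = name

    def forward(self, x, train=False, rng=None):
        if train and self.rate > 0:
            if rng is None:
                raise ValueError("dropout in training mode needs an rng")
            keep = 1.0 - self.rate
            self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
            return x * self._mask
        self._mask = None
        return x

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(
    logits: np.ndarray, y: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Class-weighted softmax cross-entropy.

    The batch loss is Σ wᵢ ℓᵢ / Σ wᵢ with wᵢ the weight of sample i's
    true class, which keeps the effective learning rate independent of
    the batch's class mix.  Returns (loss, dlogits).
    """
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    if class_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(class_weights, dtype=np.float64)[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-30, None))
    wsum = w.sum()
    loss = float(-(w * logp).sum() / wsum)
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / wsum)[:, None]
    return loss, dlogits.astype(logits.dtype)


class MomentumSGD:
    """Classical momentum: v ← μ v − η g; θ ← θ + v."""

    def __init__(self, lr: float = 0.021, momentum: float = 0.5):
        self.lr, self.momentum = lr, momentum
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self, layers: Iterable[Layer]) -> None:
        for i, layer in enumerate(layers):
            for key, p in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                v = self._v.get((i, key))
                if v is None:
                    v = np.zeros_like(p)
                v = self.momentum * v - self.lr * g
                self._v[(i, key)] = v
                p += v
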