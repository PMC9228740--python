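"""Minimal NumPy neural-network stack with reverse-mode gradients.

Implements exactly the layers the bloom segmenter needs — strided/padded 2-D
convolution (im2col), linear, layer norm, multi-head self-attention, ReLU,
fixed bilinear upsampling — each as a module with ``forward(x)`` caching what
``backward(grad)`` needs, plus masked softmax cross-entropy and Adam.  All
randomness comes from an explicit ``numpy`` Generator, so training runs are
bit-reproducible.  Convolutions are expressed as matrix products; at the
spatial sizes this package works at (feature grids of a few hundred pixels a
side at most) this is fast enough on a single CPU core.

Array conventions: images are ``(N, C, H, W)``; token sequences ``(N, T, D)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "ReLU",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "BilinearUpsample",
    "softmax",
    "masked_cross_entropy",
    "Adam",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("v", "g")

    def __init__(self, value: np.ndarray):
        self.v = np.asarray(value, dtype=np.float64)
        self.g = np.zeros_like(self.v)


class Module:
    def params(self) -> list[Param]:
        out: list[Param] = []
        for attr in vars(self).values():
            if isinstance(attr, Param):
                out.append(attr)
            elif isinstance(attr, Module):
                out.extend(attr.params())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0


def _he(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """2-D convolution with per-side padding ``(top, bottom, left, right)``."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int | tuple[int, int],
        stride: int = 1,
        padding: int | tuple[int, int, int, int] = 0,
        rng: np.random.Generator | None = None,
    ):
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        if isinstance(padding, int):
            padding = (padding, padding, padding, padding)
        self.kh, self.kw = kh, kw
        self.stride = stride
        self.pad = padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kh * kw
        self.W = Param(_he(rng, (out_ch, fan_in), fan_in))
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def out_size(self, h: int, w: int) -> tuple[int, int]:
        pt, pb, pl, pr = self.pad
        ho = (h + pt + pb - self.kh) // self.stride + 1
        wo = (w + pl + pr - self.kw) // self.stride + 1
        return ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        pt, pb, pl, pr = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        s = self.stride
        view = np.lib.stride_tricks.sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        view = view[:, :, ::s, ::s]  # (N, C, Ho, Wo, kh, kw)
        ho, wo = view.shape[2], view.shape[3]
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, -1)
        y = cols @ self.W.v.T + self.b.v
        self._cache = (cols, xp.shape, (ho, wo))
        return y.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (ho, wo) = self._cache
        n = dy.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, ho * wo, -1)
        dy2 = dyf.reshape(-1, dyf.shape[-1])
        self.W.g += dy2.T @ cols.reshape(-1, cols.shape[-1])
        self.b.g += dy2.sum(axis=0)
        dcols = (dyf @ self.W.v).reshape(n, ho, wo, -1, self.kh, self.kw)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, kh, kw)
        dxp = np.zeros(xp_shape)
        s = self.stride
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[..., i, j]
        pt, pb, pl, pr = self.pad
        h = xp_shape[2] - pt - pb
        w = xp_shape[3] - pl - pr
        return dxp[:, :, pt : pt + h, pl : pl + w]


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(_he(rng, (d_out, d_in), d_in))
        self.b = Param(np.zeros(d_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v.T + self.b.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.g += dy2.T @ x2
        self.b.g += dy2.sum(axis=0)
        return dy @ self.W.v


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(dim))
        self.beta = Param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.gamma.v + self.beta.v

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        dxhat = dy * self.gamma.v
        self.gamma.g += (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0)
        self.beta.g += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over tokens ``(N, T, D)``."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        rng = rng or np.random.default_rng(0)
        self.h = heads
        self.dh = dim // heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, d = x.shape
        return x.reshape(n, t, self.h, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * dh)

    def forward(self, x: np.ndarray) -> np.ndarray:
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = 1.0 / np.sqrt(self.dh)
        att = softmax(np.einsum("nhtd,nhsd->nhts", q, k) * scale)
        out = np.einsum("nhts,nhsd->nhtd", att, v)
        self._cache = (q, k, v, att, scale)
        return self.wo.forward(self._merge(out))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, att, scale = self._cache
        dout = self._split(self.wo.backward(dy))
        datt = np.einsum("nhtd,nhsd->nhts", dout, v)
        dv = np.einsum("nhts,nhtd->nhsd", att, dout)
        # softmax jacobian: dS = A * (dA - sum(dA * A))
        ds = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dq = np.einsum("nhts,nhsd->nhtd", ds, k) * scale
        dk = np.einsum("nhts,nhtd->nhsd", ds, q) * scale
        dx = self.wq.backward(self._merge(dq))
        dx = dx + self.wk.backward(self._merge(dk))
        dx = dx + self.wv.backward(self._merge(dv))
        return dx


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D linear interpolation matrix (align-corners endpoints)."""
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, n_in - 1, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearUpsample(Module):
    """Fixed (non-trainable) bilinear resize of ``(N, C, H, W)`` maps."""

    def __init__(self, in_hw: tuple[int, int], out_hw: tuple[int, int]):
        self.A = _interp_matrix(out_hw[0], in_hw[0])
        self.B = _interp_matrix(out_hw[1], in_hw[1])

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.matmul(np.matmul(self.A, x), self.B.T)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.matmul(np.matmul(self.A.T, dy), self.B)


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, valid: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy over valid pixels.

    Parameters
    ----------
    logits : (N, K, H, W)
    labels : (N, H, W) integer class indices (only read where valid)
    valid : (N, H, W) boolean

    Returns the scalar loss and d(loss)/d(logits).
    """
    n, k, h, w = logits.shape
    flat = logits.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.reshape(-1)
    ok = valid.reshape(-1)
    m = int(ok.sum())
    if m == 0:
        raise ValueError("no valid pixels to compute the loss on")
    p = softmax(flat, axis=-1)
    idx = np.flatnonzero(ok)
    loss = -np.log(np.maximum(p[idx, lab[idx]], 1e-12)).sum() / m
    dflat = np.zeros_like(flat)
    dflat[idx] = p[idx]
    dflat[idx, lab[idx]] -= 1.0
    dflat /= m
    dlogits = dflat.reshape(n, h, w, k).transpose(0, 3, 1, 2)
    return float(loss), dlogits


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m[...] = self.b1 * m + (1.0 - self.b1) * p.g
            s[...] = self.b2 * s + (1.0 - self.b2) * p.g**2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)
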