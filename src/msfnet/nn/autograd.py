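"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine supports exactly the operations a U-shaped segmentation network
needs: stride-1 (optionally dilated) 2-D convolution, 2x2 max pooling,
bilinear resampling, batch normalisation, elementwise nonlinearities,
channel concatenation and the reductions required by overlap losses.

Design notes
------------
* ``Tensor`` wraps a float32 ``ndarray`` and records a closure that
  propagates the upstream gradient to its parents.  ``backward`` runs a
  topological sweep over the recorded graph.
* All convolutions are stride 1, so the gradient w.r.t. the input is itself
  a (dilated) convolution of the padded upstream gradient with the
  180-degree-rotated kernel; no scatter-add is needed anywhere on the conv
  path, which keeps the engine fast enough for CPU training.
* Gradients accumulate with ``+=`` so shared parameters (e.g. one kernel
  applied at several dilation rates) receive the sum of their branch
  gradients automatically.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "relu",
    "leaky_relu",
    "softmax_channels",
    "conv2d",
    "max_pool2d",
    "avg_pool_global",
    "upsample_bilinear",
    "batch_norm",
    "dropout",
]


class Tensor:
    """A float32 array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str = ""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents
        self.name = name

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad or self._parents:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._parents:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), _parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), _parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g / n, self.data.shape))
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def reciprocal(self) -> "Tensor":
        out = Tensor(1.0 / self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g / (self.data * self.data))
        return out

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other.reciprocal()

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={'set' if self.grad is not None else 'none'})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- activations ----------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    # stable form: exp of a non-positive argument only
    e = np.exp(-np.abs(x.data))
    s = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(np.float32)
    out = Tensor(s, _parents=(x,))
    out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, _parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, slope * x.data), _parents=(x,))
    out._backward = lambda g: x._accum(g * np.where(mask, 1.0, slope).astype(np.float32))
    return out


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax across axis 1 (channels) of a (B, K, H, W) tensor."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=1, keepdims=True)
    out = Tensor(s, _parents=(x,))

    def bw(g):
        dot = (g * s).sum(axis=1, keepdims=True)
        x._accum(s * (g - dot))

    out._backward = bw
    return out


# -- concatenation --------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


# -- convolution ----------------------------------------------------------

def _conv2d_raw(x: np.ndarray, w: np.ndarray, pad: int, dilation: int) -> np.ndarray:
    """Stride-1 (dilated) cross-correlation as a sum of k*k shifted
    channel-mixing matmuls; avoids materialising an im2col matrix."""
    B, C, H, W = x.shape
    cout, cin, k, _ = w.shape
    keff = 1 + (k - 1) * dilation
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho, Wo = x.shape[2] - keff + 1, x.shape[3] - keff + 1
    # accumulate in (Cout, B, Ho, Wo) so each tap is one sgemm
    y = np.zeros((cout, B, Ho, Wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            xs = x[:, :, i * dilation: i * dilation + Ho, j * dilation: j * dilation + Wo]
            y += np.tensordot(w[:, :, i, j], xs, axes=(1, 1))
    return np.ascontiguousarray(y.transpose(1, 0, 2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0, dilation: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) with optional dilation.

    ``x`` is (B, Cin, H, W), ``w`` is (Cout, Cin, k, k), ``b`` is (Cout,).
    """
    B, Cin, H, W = x.data.shape
    cout, cin_w, k, _ = w.data.shape
    if cin_w != Cin:
        raise ValueError(f"channel mismatch: input has {Cin} channels, kernel expects {cin_w}")
    y = _conv2d_raw(x.data, w.data, padding, dilation)
    if b is not None:
        y += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)
    Ho, Wo = y.shape[2], y.shape[3]

    def bw(g):
        keff = 1 + (k - 1) * dilation
        xp = x.data
        if padding:
            xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        dw = np.empty_like(w.data)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i * dilation: i * dilation + Ho, j * dilation: j * dilation + Wo]
                dw[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
        w._accum(dw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            # dx = full correlation of g with the flipped, transposed kernel
            w_flip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            dx = _conv2d_raw(g, w_flip, keff - 1 - padding, dilation)
            x._accum(dx)

    out._backward = bw
    return out


# -- pooling --------------------------------------------------------------

def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""
    B, C, H, W = x.data.shape
    Ho, Wo = H // 2, W // 2
    xc = x.data[:, :, : Ho * 2, : Wo * 2]
    blocks = xc.reshape(B, C, Ho, 2, Wo, 2)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], _parents=(x,))

    def bw(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = np.zeros_like(x.data)
        dx[:, :, : Ho * 2, : Wo * 2] = (
            dflat.reshape(B, C, Ho, Wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho * 2, Wo * 2)
        )
        x._accum(dx)

    out._backward = bw
    return out


def avg_pool_global(x: Tensor) -> Tensor:
    """Global average pool: (B, C, H, W) -> (B, C, 1, 1)."""
    B, C, H, W = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3), keepdims=True), _parents=(x,))
    out._backward = lambda g: x._accum(np.broadcast_to(g / (H * W), x.data.shape))
    return out


# -- bilinear resampling --------------------------------------------------

def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic (n_out, n_in) bilinear interpolation matrix
    (half-pixel-centre convention, edges clamped)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(np.float32)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resample (B, C, H, W) to an arbitrary (H_out, W_out) bilinearly."""
    Ho, Wo = size
    B, C, H, W = x.data.shape
    Rh = _interp_matrix(Ho, H)
    Rw = _interp_matrix(Wo, W)
    y = np.einsum("oh,bchw,pw->bcop", Rh, x.data, Rw, optimize=True)
    out = Tensor(y, _parents=(x,))

    def bw(g):
        x._accum(np.einsum("oh,bcop,pw->bchw", Rh, g, Rw, optimize=True))

    out._backward = bw
    return out


# -- batch normalisation --------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation of a (B, C, H, W) tensor.

    Running statistics are updated in place in training mode and used
    directly in evaluation mode.
    """
    C = x.data.shape[1]
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        n = x.data.size / C
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var * (n / max(n - 1.0, 1.0))  # unbiased for the running estimate
    else:
        mean, var = running_mean, running_var
    inv = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    scale = (gamma.data * inv).reshape(1, C, 1, 1)
    shift = (beta.data - gamma.data * inv * mean).reshape(1, C, 1, 1).astype(np.float32)
    y = x.data * scale
    y += shift
    out = Tensor(y, _parents=(x, gamma, beta))

    def bw(g):
        xhat = (x.data - mean.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        gi = g * gamma.data.reshape(1, C, 1, 1)
        if training:
            n = x.data.size / C
            invr = inv.reshape(1, C, 1, 1)
            sum_gi = gi.sum(axis=(0, 2, 3), keepdims=True)
            sum_gx = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (gi - sum_gi / n - xhat * sum_gx / n) * invr
        else:
            dx = gi * inv.reshape(1, C, 1, 1)
        x._accum(dx)

    out._backward = bw
    return out


# -- dropout --------------------------------------------------------------

def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = 1.0 - p
    mask = (rng.random(x.data.shape) < keep).astype(np.float32) / keep
    out = Tensor(x.data * mask, _parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out
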