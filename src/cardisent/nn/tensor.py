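"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations the model needs are implemented: broadcasting
arithmetic, matrix multiplication, 2-D convolution (im2col), pooling,
nearest-neighbour upsampling, pointwise nonlinearities, reductions,
reshapes/concatenation/indexing, and a straight-through rounding used to
binarize the spatial factor.  All arrays are float32; gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks a
topologically sorted tape.  Gradients of every primitive are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "avg_pool2d",
    "upsample_nearest2d",
    "softmax",
    "log_clamped",
]

_F32 = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_F32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
            if self.grad.shape != self.data.shape:  # defensive; ops unbroadcast
                self.grad = np.broadcast_to(g, self.data.shape).astype(self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=_F32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # drop intermediate grads/tape references eagerly
            if not node.requires_grad and node is not self:
                node._backward = None

    # ------------------------------------------------------------- op helpers
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.shape)
            )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            self._accumulate(g * p * np.power(self.data, p - 1))

        return Tensor._make(np.power(self.data, p), (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # ---------------------------------------------------------- nonlinearities
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g / (2.0 * out_data))

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), bw)

    def leaky_relu(self, alpha: float = 0.2):
        mask = self.data > 0
        scale = np.where(mask, 1.0, alpha).astype(_F32)

        def bw(g):
            self._accumulate(g * scale)

        return Tensor._make(self.data * scale, (self,), bw)

    def abs(self):
        sign = np.sign(self.data).astype(_F32)

        def bw(g):
            self._accumulate(g * sign)

        return Tensor._make(np.abs(self.data), (self,), bw)

    def clip(self, lo: float, hi: float):
        inside = ((self.data > lo) & (self.data < hi)).astype(_F32)

        def bw(g):
            self._accumulate(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), bw)

    def maximum(self, other):
        other = as_tensor(other)
        take_self = (self.data >= other.data).astype(_F32)

        def bw(g):
            self._accumulate(_unbroadcast(g * take_self, self.shape))
            other._accumulate(_unbroadcast(g * (1.0 - take_self), other.shape))

        return Tensor._make(np.maximum(self.data, other.data), (self, other), bw)

    def round_ste(self, threshold: float = 0.5):
        """Hard-threshold forward, identity (straight-through) backward."""

        def bw(g):
            self._accumulate(g)

        return Tensor._make((self.data > threshold).astype(_F32), (self,), bw)

    # --------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).astype(_F32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(_F32))

        return Tensor._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accumulate(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, idx):
        fancy = isinstance(idx, np.ndarray) or (
            isinstance(idx, tuple)
            and any(isinstance(i, (np.ndarray, list)) for i in idx)
        )

        def bw(g):
            full = np.zeros_like(self.data)
            if fancy:  # duplicate indices must accumulate
                np.add.at(full, idx, g)
            else:
                full[idx] += g
            self._accumulate(full)

        return Tensor._make(self.data[idx], (self,), bw)

    def index_select0(self, indices: np.ndarray):
        """Gather rows along axis 0 (used for in-batch permutations)."""
        indices = np.asarray(indices)
        return self[indices]


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
    )


# ----------------------------------------------------------------- conv ops
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(B,C,H,W) -> (B, Ho*Wo, C*kh*kw) patches."""
    b, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (B,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int) -> np.ndarray:
    b, c, h, w = x_shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    # (B, Ho, Wo, C, kh, kw) is a free view of (B, P, C*kh*kw)
    patches = cols.reshape(b, ho, wo, c, kh, kw)
    out = np.zeros(x_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                patches[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return out


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int | str = "same",
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW input, OIHW weights."""
    x, w = as_tensor(x), as_tensor(w)
    _, cin, kh, kw = w.shape
    if x.shape[1] != cin:
        raise ValueError(f"conv2d: expected {cin} input channels, got {x.shape[1]}")
    if padding == "same":
        if stride != 1:
            raise ValueError("padding='same' requires stride 1")
        pad = (kh - 1) // 2
    else:
        pad = int(padding)
    xd = x.data
    if pad:
        xd = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    bsz, _, hp, wp = xd.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = _im2col(xd, kh, kw, stride)  # (B, P, CKK)
    wmat = w.data.reshape(w.shape[0], -1)  # (O, CKK)
    out_data = cols @ wmat.T  # (B, P, O)
    if b is not None:
        out_data = out_data + b.data[None, None, :]
    out_data = out_data.transpose(0, 2, 1).reshape(bsz, w.shape[0], ho, wo)

    padded_shape = xd.shape
    need_dx = x.requires_grad or bool(x._parents)
    need_dw = w.requires_grad or bool(w._parents)

    def bw(g):
        gmat = np.ascontiguousarray(
            g.reshape(bsz, w.shape[0], ho * wo).transpose(0, 2, 1)
        ).reshape(bsz * ho * wo, w.shape[0])  # (B*P, O)
        if need_dw:
            colsflat = cols.reshape(bsz * ho * wo, -1)  # (B*P, CKK)
            w._accumulate((gmat.T @ colsflat).reshape(w.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if need_dx:
            if stride == 1:
                # dX as a correlation of g with the rotated, transposed
                # kernel: one im2col + matmul instead of a scatter-add
                q = kh - 1 - pad
                gp = g if q == 0 else np.pad(
                    g, ((0, 0), (0, 0), (q, q), (q, q))
                )
                colsg = _im2col(gp, kh, kw, 1)  # (B, H*W, O*kh*kw)
                w2 = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                ).reshape(cin, -1)
                dx = (colsg @ w2.T).transpose(0, 2, 1).reshape(
                    bsz, cin, x.shape[2], x.shape[3]
                )
                x._accumulate(dx)
            else:
                dcols = (gmat @ wmat).reshape(bsz, ho * wo, -1)  # (B,P,CKK)
                dxp = _col2im(dcols, padded_shape, kh, kw, stride)
                if pad:
                    dxp = dxp[:, :, pad:-pad, pad:-pad]
                x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, bw)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused batch normalization over (B, H, W) per channel.

    Returns (out, batch_mean, batch_var) with a hand-derived backward; a
    single primitive keeps the tape short on the hottest path.
    """
    xd = x.data
    axes = (0, 2, 3)
    n = xd.shape[0] * xd.shape[2] * xd.shape[3]
    mu = xd.mean(axis=axes, keepdims=True)
    xc = xd - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def bw(g):
        gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
        beta._accumulate(g.sum(axis=axes, keepdims=True))
        gh = g * gamma.data  # dL/dxhat
        t1 = gh - gh.mean(axis=axes, keepdims=True)
        t2 = xhat * (gh * xhat).mean(axis=axes, keepdims=True)
        x._accumulate(((t1 - t2) * inv).astype(_F32))

    out = Tensor._make(out_data, (x, gamma, beta), bw)
    return out, mu, var


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("avg_pool2d: spatial size must be divisible by k")
    out_data = x.data.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def bw(g):
        gg = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        x._accumulate(gg.astype(_F32))

    return Tensor._make(out_data, (x,), bw)


def upsample_nearest2d(x: Tensor, k: int = 2) -> Tensor:
    b, c, h, w = x.shape
    out_data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)

    def bw(g):
        gg = g.reshape(b, c, h, k, w, k).sum(axis=(3, 5))
        x._accumulate(gg)

    return Tensor._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_clamped(x: Tensor, floor: float = 1e-8) -> Tensor:
    """log with the argument clamped below at ``floor``."""
    return x.maximum(Tensor(np.full_like(x.data, floor))).log()
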