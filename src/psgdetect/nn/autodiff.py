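"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray together with a gradient slot and a
backward closure; operations build a DAG whose reverse topological sweep
accumulates gradients.  Only the primitives needed for a 1-D segmentation
network are provided: broadcast arithmetic, matmul, elementwise nonlinear
functions, reductions, shape ops, same-padding 1-D convolution, max pooling
and nearest-neighbor upsampling.  Gradient correctness is pinned down by
finite-difference tests rather than by construction.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "concat", "no_grad", "set_dtype", "get_dtype"]

_grad_enabled = True
_dtype = np.float32


def set_dtype(dtype) -> None:
    """Set the global compute dtype (float32 default; float64 for checks)."""
    global _dtype
    _dtype = np.dtype(dtype).type


def get_dtype():
    return _dtype


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # Stores without copying: backward closures only hand over arrays they
        # own, or views of gradients already consumed by the reverse sweep.
        if self.grad is None:
            self.grad = np.asarray(grad, dtype=self.data.dtype)
        else:
            self.grad = self.grad + grad if not self.grad.flags.writeable else self.grad.__iadd__(grad)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures once consumed

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                gb = _unbroadcast(g, b.shape)
                # both parents may receive the identical array; keep them distinct
                if a.requires_grad and gb is a.grad:
                    gb = gb.copy()
                b._accum(gb)

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a.requires_grad and a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(np.matmul(g, np.swapaxes(b.data, -1, -2)), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), backward)

    def __pow__(self, p: float):
        a = self

        def backward(g):
            a._accum(g * p * a.data ** (p - 1))

        return Tensor._make(a.data**p, (a,), backward)

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accum(g * mask))

    def softmax(self, axis: int = -1):
        """Fused, numerically stable softmax along ``axis``."""
        a = self
        shifted = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum(out_data * (g - dot))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        from scipy.special import expit

        a = self
        out_data = expit(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * out_data * (1 - out_data)))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy() if np.ndim(g) else np.full(a.shape, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[i] for i in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max as a constant (used for numerically stable softmax)."""
        return self.data.max(axis=axis, keepdims=keepdims)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        a = self
        return Tensor._make(
            a.data.reshape(*shape), (a,), lambda g: a._accum(g.reshape(a.shape))
        )

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(*axes), (a,), lambda g: a._accum(g.transpose(*inv))
        )

    # -- structured ops -------------------------------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None) -> "Tensor":
        """Same-padding cross-correlation along the last axis.

        input (B, C_in, L), weight (C_out, C_in, K) with K odd -> (B, C_out, L).
        """
        x, w = self, weight
        B, C, L = x.shape
        Co, Ci, K = w.shape
        if Ci != C:
            raise ValueError(f"weight expects {Ci} input channels, got {C}")
        if K % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        pad = K // 2
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
        # K shift-multiplies instead of an im2col matrix: same arithmetic,
        # no (B, C*K, L) materialization
        y = np.matmul(w.data[:, :, 0], xp[:, :, :L])
        for k in range(1, K):
            y += np.matmul(w.data[:, :, k], xp[:, :, k : k + L])
        if bias is not None:
            y += bias.data[None, :, None]
        parents = (x, w) if bias is None else (x, w, bias)

        def backward(g):
            if w.requires_grad:
                dw = np.empty((Co, C, K))
                for k in range(K):
                    dw[:, :, k] = np.tensordot(g, xp[:, :, k : k + L], axes=([0, 2], [0, 2]))
                w._accum(dw)
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                wt = w.data.transpose(2, 1, 0)  # (K, C, Co)
                for k in range(K):
                    dxp[:, :, k : k + L] += np.matmul(wt[k], g)
                x._accum(dxp[:, :, pad : pad + L])

        return Tensor._make(y, parents, backward)

    def maxpool1d(self, factor: int) -> "Tensor":
        """Non-overlapping max pooling along the last axis."""
        a = self
        B, C, L = a.shape
        if L % factor:
            raise ValueError(f"length {L} not divisible by pool factor {factor}")
        blocks = a.data.reshape(B, C, L // factor, factor)
        idx = blocks.argmax(axis=-1)
        out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            db = np.zeros_like(blocks)
            np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
            a._accum(db.reshape(B, C, L))

        return Tensor._make(out_data, (a,), backward)

    def upsample_nearest(self, factor: int) -> "Tensor":
        """Repeat each sample ``factor`` times along the last axis."""
        a = self
        B, C, L = a.shape

        def backward(g):
            a._accum(g.reshape(B, C, L, factor).sum(axis=-1))

        return Tensor._make(np.repeat(a.data, factor, axis=-1), (a,), backward)


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch normalization over axes (0, 2) of (B, C, L).

    Returns the normalized output and the batch mean/variance (constants, for
    running-average updates).  Fusing the whole normalization into one node
    keeps the elementwise traffic of the backward pass low.
    """
    B, C, L = x.shape
    n = B * L
    mu = x.data.mean(axis=(0, 2))
    xc = x.data - mu[None, :, None]
    var = np.einsum("bcl,bcl->c", xc, xc) / n
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = xc * ivar[None, :, None]
    y = xhat * gamma.data[None, :, None] + beta.data[None, :, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum(np.einsum("bcl,bcl->c", g, xhat))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            dxhat = g * gamma.data[None, :, None]
            s1 = dxhat.sum(axis=(0, 2))[None, :, None]
            s2 = np.einsum("bcl,bcl->c", dxhat, xhat)[None, :, None]
            x._accum(ivar[None, :, None] / n * (n * dxhat - s1 - xhat * s2))

    return Tensor._make(y, (x, gamma, beta), backward), mu, var


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), backward)
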