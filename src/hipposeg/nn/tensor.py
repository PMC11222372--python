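"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives a 3D U-shaped segmentation
network needs: broadcast-aware arithmetic, batched matmul, axis
reductions (sum / mean / max), shape ops, pointwise nonlinearities, and
dedicated 3D convolution / transposed-convolution / max-pooling ops with
hand-written adjoints.  Gradients are accumulated by a topological sweep
over the recorded tape.

Arrays are kept in whatever float dtype they were created with; training
code uses float32, correctness tests use float64.
"""

from __future__ import annotations

import contextlib
import math
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording (inference / weight updates)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction -------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Sequence["Tensor"],
                backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd driver ----------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without gradient only allowed for scalars")
            grad = np.ones_like(self.data)
        # iterative topological order
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("1-D matmul operands unsupported")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.shape))
            other._accum(_unbroadcast(gb, other.shape))

        return Tensor._result(out_data, (self, other), backward)

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._result(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis, keepdims: bool = False):
        """Max reduction; ties share the incoming gradient equally."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis) if not isinstance(axis, tuple) else \
                    np.reshape(g, out_data.shape)
            self._accum(mask * (g / counts))

        data = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._result(data, (self,), backward)

    # -- pointwise nonlinearities -----------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return Tensor._result(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._result(out_data, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        out_data = x * cdf

        def backward(g):
            pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
            self._accum(g * (cdf + x * pdf))

        return Tensor._result(out_data, (self,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return Tensor._result(out_data, tensors, backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along `axis` (max shift is detached)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- structured 3D ops ----------------------------------------------------

#: im2col buffers above this many bytes fall back to the offset loop
_IM2COL_LIMIT = 32 * 1024 * 1024


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, padding: int) -> Tensor:
    """3D cross-correlation, stride 1, symmetric zero padding.

    x: (B, Ci, D, H, W); w: (Co, Ci, k, k, k); b: (Co,) or None.
    Small problems use an im2col matmul; large ones a memory-light loop
    over kernel offsets.
    """
    xd, wd = x.data, w.data
    co, ci, k, _, _ = wd.shape
    p = padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    B, _, Dp, Hp, Wp = xp.shape
    Do, Ho, Wo = Dp - k + 1, Hp - k + 1, Wp - k + 1
    P = Do * Ho * Wo
    k3 = k ** 3
    parents = (x, w) if b is None else (x, w, b)
    use_im2col = B * P * ci * k3 * xd.itemsize <= _IM2COL_LIMIT

    if use_im2col:
        view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                        axis=(2, 3, 4))
        cols = view.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(B, P, ci * k3)
        wmat = wd.reshape(co, ci * k3).T            # (Ci*k^3, Co)
        out = (cols @ wmat).transpose(0, 2, 1).reshape(B, co, Do, Ho, Wo)
        if b is not None:
            out += b.data.reshape(1, co, 1, 1, 1)

        def backward(g):
            if b is not None:
                b._accum(g.sum(axis=(0, 2, 3, 4)))
            gm = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(B * P, co)
            if w.requires_grad:
                dw = (cols.reshape(B * P, ci * k3).T @ gm).T.reshape(wd.shape)
                w._accum(dw)
            if x.requires_grad:
                dcols = (gm @ wmat.T).reshape(B, Do, Ho, Wo, ci, k, k, k)
                dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)
                dxp = np.zeros_like(xp)
                for a in range(k):
                    for bb in range(k):
                        for c in range(k):
                            dxp[:, :, a:a + Do, bb:bb + Ho, c:c + Wo] += \
                                dcols[..., a, bb, c]
                sl = slice(p, -p) if p else slice(None)
                x._accum(dxp[:, :, sl, sl, sl])

        return Tensor._result(out, parents, backward)

    # offset-loop path: one channel-mixing matmul per kernel offset
    out = np.zeros((B, co, Do, Ho, Wo), dtype=xd.dtype)
    wflat = wd.reshape(co, ci, k3)
    for o in range(k3):
        a, r = divmod(o, k * k)
        bb, c = divmod(r, k)
        patch = xp[:, :, a:a + Do, bb:bb + Ho, c:c + Wo].reshape(B, ci, -1)
        out += (wflat[:, :, o] @ patch).reshape(B, co, Do, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, co, 1, 1, 1)

    def backward(g):
        gm = g.reshape(B, co, -1)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        dw = np.zeros_like(wd)
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for o in range(k3):
            a, r = divmod(o, k * k)
            bb, c = divmod(r, k)
            patch = xp[:, :, a:a + Do, bb:bb + Ho, c:c + Wo].reshape(B, ci, -1)
            if w.requires_grad:
                dw.reshape(co, ci, k3)[:, :, o] = np.einsum(
                    "bop,bip->oi", gm, patch, optimize=True)
            if dxp is not None:
                dpatch = np.swapaxes(wflat[:, :, o], 0, 1) @ gm
                dxp[:, :, a:a + Do, bb:bb + Ho, c:c + Wo] += dpatch.reshape(
                    B, ci, Do, Ho, Wo)
        if w.requires_grad:
            w._accum(dw)
        if dxp is not None:
            sl = slice(p, -p) if p else slice(None)
            x._accum(dxp[:, :, sl, sl, sl])

    return Tensor._result(out, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed 3D convolution with kernel 2, stride 2 (exact doubling).

    x: (B, Ci, D, H, W); w: (Ci, Co, 2, 2, 2); output (B, Co, 2D, 2H, 2W).
    """
    xd, wd = x.data, w.data
    B, ci, D, H, W = xd.shape
    co = wd.shape[1]
    t = np.einsum("bidhw,ioxyz->bodxhywz", xd, wd, optimize=True)
    out = t.reshape(B, co, 2 * D, 2 * H, 2 * W)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gr = g.reshape(B, co, D, 2, H, 2, W, 2)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            x._accum(np.einsum("bodxhywz,ioxyz->bidhw", gr, wd, optimize=True))
        if w.requires_grad:
            w._accum(np.einsum("bidhw,bodxhywz->ioxyz", xd, gr, optimize=True))

    return Tensor._result(out, parents, backward)


def maxpool3d(x: Tensor) -> Tensor:
    """Max pooling, kernel 2, stride 2. Spatial dims must be even."""
    B, C, D, H, W = x.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool3d requires even spatial dims, got {(D, H, W)}")
    r = x.data.reshape(B, C, D // 2, 2, H // 2, 2, W // 2, 2)
    r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, D // 2, H // 2, W // 2, 8)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(B, C, D // 2, H // 2, W // 2, 2, 2, 2)
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, D, H, W)
        x._accum(gr)

    return Tensor._result(out, (x,), backward)
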