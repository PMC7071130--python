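"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute core of the package: a tape-based autodiff engine with
exactly the operations the MLA-CNN-BiGRU network needs (broadcast-aware
elementwise arithmetic, batched matmul, 2D convolution, overlapping max
pooling, batch normalization, softmax, and the clipped StepReLU activation).
Gradient correctness of every primitive is pinned against central finite
differences in the test suite.

Design notes
------------
* ``Tensor`` wraps a numpy array.  Operations build a DAG; ``backward()``
  runs a topological sweep accumulating ``.grad`` buffers (allocated lazily,
  once per tensor, so long unrolled recurrences stay memory-bounded).
* ``no_grad()`` disables graph construction for inference passes.
* Convolution is evaluated as a sum of per-offset GEMMs over shifted views
  of the zero-padded input ("shift-and-matmul"), which keeps peak memory at
  one activation copy instead of a full im2col buffer.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "stack",
    "conv2d",
    "maxpool2x2",
    "batchnorm_train",
    "softmax",
    "step_relu",
    "step_relu_grad",
]

_GRAD_ENABLED = True
_ALLOCATOR_TUNED = False


def tune_allocator() -> None:
    """Keep large numpy buffers on the process heap (glibc only).

    By default glibc serves every multi-megabyte allocation with a fresh
    ``mmap``, so each training step pays soft page faults for hundreds of
    megabytes of transient activations.  Raising the mmap and trim
    thresholds lets freed blocks be reused, which speeds conv-sized
    workloads up several-fold.  No-op on non-glibc platforms.
    """
    global _ALLOCATOR_TUNED
    if _ALLOCATOR_TUNED:
        return
    _ALLOCATOR_TUNED = True
    try:
        import ctypes
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, 1 << 28)  # M_TRIM_THRESHOLD
    except Exception:
        pass


@contextlib.contextmanager
def no_grad():
    """Context manager: operations inside build no graph."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(grad, self.data.shape))
        else:
            self.grad += grad

    # -- basic protocol -------------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __radd__ = __add__

    def __neg__(self):
        def backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), backward)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by python scalars")
        return self * (1.0 / scalar)

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward():
            g = out.grad
            if a.ndim == 1 and b.ndim == 1:  # inner product
                if self.requires_grad:
                    self._accum(g * b)
                if other.requires_grad:
                    other._accum(g * a)
                return
            if b.ndim == 1:  # (..., m, k) @ (k,) -> (..., m)
                if self.requires_grad:
                    self._accum(g[..., None] * b)
                if other.requires_grad:
                    other._accum(np.tensordot(
                        g, self.data,
                        axes=(tuple(range(g.ndim)), tuple(range(g.ndim)))))
                return
            if a.ndim == 1:  # (k,) @ (..., k, n) -> (..., n)
                if self.requires_grad:
                    self._accum(np.tensordot(g, other.data,
                                             axes=(tuple(range(g.ndim)),
                                                   tuple(range(g.ndim - 1)) + (g.ndim,))))
                if other.requires_grad:
                    other._accum(_unbroadcast(a[..., :, None] * g[..., None, :], b.shape))
                return
            # general batched matmul
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    # -- shaping --------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        out = Tensor._make(self.data.reshape(shape), (self,), backward)
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    def __getitem__(self, idx):
        def backward():
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[idx] += out.grad

        out = Tensor._make(self.data[idx], (self,), backward)
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out = Tensor._make(out_data, (self,), backward)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)

        def backward():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - y * y))

        out = Tensor._make(y, (self,), backward)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward():
            if self.requires_grad:
                self._accum(out.grad * y * (1.0 - y))

        out = Tensor._make(y, (self,), backward)
        return out

    def relu(self):
        mask = self.data > 0

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(self.data * mask, (self,), backward)
        return out

    def log(self):
        def backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), backward)
        return out

    def clip_min(self, lo: float):
        """max(x, lo) with pass-through gradient where x > lo."""
        mask = self.data > lo

        def backward():
            if self.requires_grad:
                self._accum(out.grad * mask)

        out = Tensor._make(np.maximum(self.data, lo), (self,), backward)
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("called backward() on a tensor without grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative post-order DFS (recursion would overflow on 651-step RNNs)
        visit: list[tuple[Tensor, bool]] = [(self, False)]
        while visit:
            node, processed = visit.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visit.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    visit.append((p, False))
        del stack_
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
                # retire the node: free its closure and gradient buffer so
                # activation memory is released as the sweep walks the tape
                # (leaf tensors — parameters and inputs — keep their grads)
                node._backward = None
                node._parents = ()
                if node is not self:
                    node.grad = None


# -- free functions -----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out_data.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out = Tensor._make(out_data, tensors, backward)
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward():
        for i, t in enumerate(tensors):
            if t.requires_grad:
                idx = [slice(None)] * out_data.ndim
                idx[axis] = i
                t._accum(out.grad[tuple(idx)])

    out = Tensor._make(out_data, tensors, backward)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward():
        if x.requires_grad:
            g = out.grad
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - dot))

    out = Tensor._make(s, (x,), backward)
    return out


def step_relu(x):
    """Clipped-linear activation: 0 for x<0, x on [0,1], 1 for x>1.

    Accepts a Tensor (differentiable) or a plain array/scalar.
    """
    if not isinstance(x, Tensor):
        return np.clip(x, 0.0, 1.0)
    mask = (x.data >= 0) & (x.data <= 1)

    def backward():
        if x.requires_grad:
            x._accum(out.grad * mask)

    out = Tensor._make(np.clip(x.data, 0.0, 1.0), (x,), backward)
    return out


def step_relu_grad(x):
    """Exact subgradient of ``step_relu``: 1 on [0, 1] (corners included), else 0."""
    x = np.asarray(x)
    return ((x >= 0) & (x <= 1)).astype(x.dtype if x.dtype.kind == "f" else float)


_SCRATCH: dict = {}


def _scratch(shape: tuple, dtype) -> np.ndarray:
    """Reusable scratch buffer (single-threaded use within one operation)."""
    key = (shape, np.dtype(dtype).str)
    buf = _SCRATCH.get(key)
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        if len(_SCRATCH) > 32:  # avoid unbounded growth across batch shapes
            _SCRATCH.clear()
        _SCRATCH[key] = buf
    return buf


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2D cross-correlation with SAME zero padding, stride 1.

    Channels-last convention: x is (B, H, W, C), w is (O, C, kh, kw) with
    odd kernel dims, b is (O,).  Returns (B, H, W, O).  Evaluated as one
    GEMM per kernel offset over shifted slices of the padded input, which
    keeps peak memory at a single activation copy.
    """
    B, H, W, C = x.data.shape
    O, C2, kh, kw = w.data.shape
    if C2 != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    if kh > H or kw > W:
        raise ValueError(f"kernel ({kh},{kw}) larger than input ({H},{W})")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel dims must be odd for SAME padding")
    ph, pw = kh // 2, kw // 2
    dt = x.data.dtype
    xpad = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    xsbuf = _scratch((B, H, W, C), dt)
    xs = xsbuf.reshape(-1, C)
    gemm = _scratch((B * H * W, O), dt)
    out_flat = np.zeros((B * H * W, O), dtype=dt)
    for di in range(kh):
        for dj in range(kw):
            np.copyto(xsbuf, xpad[:, di:di + H, dj:dj + W, :])
            np.matmul(xs, w.data[:, :, di, dj].T, out=gemm)
            out_flat += gemm
    if b is not None:
        out_flat += b.data
    out_data = out_flat.reshape(B, H, W, O)

    def backward():
        g = np.ascontiguousarray(out.grad).reshape(B * H * W, O)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))
        if w.requires_grad or x.requires_grad:
            gw = np.empty_like(w.data) if w.requires_grad else None
            gxpad = np.zeros_like(xpad) if x.requires_grad else None
            xsbuf = _scratch((B, H, W, C), dt)
            xs = xsbuf.reshape(-1, C)
            dxs = _scratch((B * H * W, C), dt)
            for di in range(kh):
                for dj in range(kw):
                    if gw is not None:
                        np.copyto(xsbuf, xpad[:, di:di + H, dj:dj + W, :])
                        gw[:, :, di, dj] = g.T @ xs
                    if gxpad is not None:
                        np.matmul(g, w.data[:, :, di, dj], out=dxs)
                        gxpad[:, di:di + H, dj:dj + W, :] += \
                            dxs.reshape(B, H, W, C)
            if gw is not None:
                w._accum(gw)
            if gxpad is not None:
                x._accum(gxpad[:, ph:ph + H, pw:pw + W, :])

    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, backward)
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """Overlapping 2x2 max pooling with stride 1, valid padding.

    Channels-last: (B, H, W, C) -> (B, H-1, W-1, C); ties route the
    gradient to the first maximal window position in raster order.
    """
    B, H, W, C = x.data.shape
    if H < 2 or W < 2:
        raise ValueError(f"map ({H},{W}) smaller than 2x2 pooling window")
    shifts = [x.data[:, :-1, :-1, :], x.data[:, :-1, 1:, :],
              x.data[:, 1:, :-1, :], x.data[:, 1:, 1:, :]]
    out_data = np.maximum(np.maximum(shifts[0], shifts[1]),
                          np.maximum(shifts[2], shifts[3]))

    def backward():
        g = out.grad
        gx = np.zeros_like(x.data)
        taken = np.zeros(out_data.shape, dtype=bool)
        slices = [(slice(None, -1), slice(None, -1)),
                  (slice(None, -1), slice(1, None)),
                  (slice(1, None), slice(None, -1)),
                  (slice(1, None), slice(1, None))]
        for s, (si, sj) in zip(shifts, slices):
            mask = (s == out_data) & ~taken
            gx[:, si, sj, :] += g * mask
            taken |= mask
        x._accum(gx)

    out = Tensor._make(out_data, (x,), backward)
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
                    eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Batch normalization in training mode over reduction ``axes``.

    Returns (normalized tensor, batch mean, batch var) — the caller owns the
    running-statistics update.  gamma/beta are broadcast-shaped.
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    var = (x.data * x.data).mean(axis=axes, keepdims=True) - mu * mu
    var = np.maximum(var, 0.0)  # guard against cancellation
    istd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * istd
    out_data = gamma.data * xhat + beta.data
    n = float(np.prod([x.data.shape[a] for a in axes]))

    def backward():
        g = out.grad
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if x.requires_grad:
            gh = g * gamma.data
            s1 = gh.sum(axis=axes, keepdims=True)
            s2 = (gh * xhat).sum(axis=axes, keepdims=True)
            x._accum((istd / n) * (n * gh - s1 - xhat * s2))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out, mu.squeeze(), var.squeeze()
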