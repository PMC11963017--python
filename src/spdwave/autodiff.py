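"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The geometric layers of this package differentiate through convolutions,
symmetric eigendecompositions and ordinary dense algebra.  This module
provides exactly the tape that is needed: a :class:`Tensor` wrapping a
``float64`` ndarray, a small set of primitive operations with hand-written
adjoints, and topological-order backpropagation.  It is deliberately tiny —
no views-with-aliasing, no in-place semantics, no dtype zoo — which keeps the
adjoints auditable against finite differences (see the gradient-check tests).

Conventions
-----------
* ``Tensor.data`` is always a ``numpy.float64`` ndarray; complex signals are
  carried as explicit (real, imaginary) pairs by the callers.
* Broadcasting follows NumPy; gradients are summed back to parent shapes.
* ``backward()`` may be called on any scalar Tensor.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    #: make ndarray <op> Tensor defer to the reflected Tensor methods
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- op constructor ----------------------------------------------------
    @staticmethod
    def _op(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a.accumulate(_unbroadcast(g, a.shape))
            b.accumulate(_unbroadcast(g, b.shape))

        return Tensor._op(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g, a=self):
            a.accumulate(-g)

        return Tensor._op(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a.accumulate(_unbroadcast(g * b.data, a.shape))
            b.accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._op(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            a.accumulate(_unbroadcast(g / b.data, a.shape))
            b.accumulate(_unbroadcast(-g * a.data / b.data**2, b.shape))

        return Tensor._op(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if isinstance(exponent, Tensor):
            raise TypeError("only scalar exponents are supported")

        def bw(g, a=self, n=float(exponent)):
            a.accumulate(g * n * a.data ** (n - 1.0))

        return Tensor._op(self.data**exponent, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g, a=self, b=other):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a.accumulate(_unbroadcast(ga, a.shape))
            b.accumulate(_unbroadcast(gb, b.shape))

        return Tensor._op(self.data @ other.data, (self, other), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g, a=self, old=old):
            a.accumulate(g.reshape(old))

        return Tensor._op(self.data.reshape(shape), (self,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        def bw(g, a=self, ax1=ax1, ax2=ax2):
            a.accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._op(np.swapaxes(self.data, ax1, ax2), (self,), bw)

    @property
    def mT(self):
        return self.swapaxes(-1, -2)

    def __getitem__(self, idx):
        def bw(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a.accumulate(full)

        return Tensor._op(self.data[idx], (self,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, a=self, axis=axis, keepdims=keepdims):
            if axis is None:
                a.accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a.accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g, a=self, o=out_data):
            a.accumulate(g * o)

        return Tensor._op(out_data, (self,), bw)

    def log(self):
        def bw(g, a=self):
            a.accumulate(g / a.data)

        return Tensor._op(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g, a=self, o=out_data):
            a.accumulate(g * 0.5 / o)

        return Tensor._op(out_data, (self,), bw)

    def cos(self):
        def bw(g, a=self):
            a.accumulate(-g * np.sin(a.data))

        return Tensor._op(np.cos(self.data), (self,), bw)

    def sin(self):
        def bw(g, a=self):
            a.accumulate(g * np.cos(a.data))

        return Tensor._op(np.sin(self.data), (self,), bw)

    def erf(self):
        def bw(g, a=self):
            a.accumulate(g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data**2))

        return Tensor._op(special.erf(self.data), (self,), bw)

    def sigmoid(self):
        out_data = special.expit(self.data)

        def bw(g, a=self, o=out_data):
            a.accumulate(g * o * (1.0 - o))

        return Tensor._op(out_data, (self,), bw)

    def clamp_min(self, floor: float):
        """Elementwise max(x, floor); gradient is zero below the floor."""
        mask = self.data > floor

        def bw(g, a=self, mask=mask):
            a.accumulate(g * mask)

        return Tensor._op(np.maximum(self.data, floor), (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, ts=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    return Tensor._op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bw(g, ts=tensors, axis=axis):
        for i, t in enumerate(ts):
            t.accumulate(np.take(g, i, axis=axis))

    return Tensor._op(np.stack([t.data for t in tensors], axis=axis), tensors, bw)


def eigh(X: Tensor, jitter: float = 0.0) -> tuple[Tensor, Tensor]:
    """Batched symmetric eigendecomposition with the standard adjoint.

    Returns eigenvalues ``w`` (ascending) and eigenvectors ``V`` so that
    ``X = V diag(w) V^T``.  The adjoint uses the textbook formula with safe
    reciprocals of eigenvalue gaps; near-degenerate pairs get zero coupling,
    optionally after adding ``jitter`` to the input diagonal.
    """
    X = as_tensor(X)
    A = 0.5 * (X.data + np.swapaxes(X.data, -1, -2))
    if jitter:
        A = A + jitter * np.eye(A.shape[-1])
    w, V = np.linalg.eigh(A)

    def _sym(M):
        return 0.5 * (M + np.swapaxes(M, -1, -2))

    def bw_w(g, X=X, w=w, V=V):
        gw = g[..., None] * np.swapaxes(V, -1, -2)
        X.accumulate(_sym(V @ gw))

    def bw_V(g, X=X, w=w, V=V):
        diff = w[..., None, :] - w[..., :, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(np.abs(diff) > 1e-12, 1.0 / diff, 0.0)
        inner = np.swapaxes(V, -1, -2) @ g
        X.accumulate(_sym(V @ (F * inner) @ np.swapaxes(V, -1, -2)))

    tw = Tensor._op(w, (X,), bw_w)
    tV = Tensor._op(V, (X,), bw_V)
    return tw, tV


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit, exact (erf) form."""
    return x * 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)
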