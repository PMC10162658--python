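"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tape-based autodiff to express and train the capsule network:
broadcasting arithmetic, matmul, two-operand einsum, strided 1-D
convolution, reductions, reshapes, slicing, concatenation and the usual
pointwise nonlinearities.  Gradients are accumulated in float64; every op
is covered by numerical-gradient tests.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / other.data**2, other.shape)
                    )
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = _node(self.data**exponent, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * exponent * self.data ** (exponent - 1)
            )
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bwd(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accumulate(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accumulate(_unbroadcast(gb, other.shape))
            out._backward = bwd
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out = _node(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def transpose(self, axes: Sequence[int]):
        inv = np.argsort(axes)
        out = _node(self.data.transpose(axes), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def __getitem__(self, key):
        out = _node(self.data[key], (self,))
        if out.requires_grad:
            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accumulate(full)
            out._backward = bwd
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bwd(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    # -- pointwise nonlinearities ------------------------------------------
    def exp(self):
        val = np.exp(self.data)
        out = _node(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = _node(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / (2.0 * val))
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = _node(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * (1.0 - val * val))
        return out

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-self.data))
        out = _node(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def relu(self):
        mask = self.data > 0
        out = _node(self.data * mask, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out


def _node(data: np.ndarray, parents: Tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # max-shift is a constant under the gradient (softmax is shift-invariant)
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def einsum(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum.

    Restricted to specs where every index of each operand also appears in
    the other operand or in the output (true for all uses here), so each
    operand's gradient is itself a two-operand einsum.
    """
    a, b = as_tensor(a), as_tensor(b)
    inputs, out_spec = spec.split("->")
    sa, sb = inputs.split(",")
    out = _node(np.einsum(spec, a.data, b.data, optimize=True), (a, b))
    if out.requires_grad:
        def bwd(g):
            if a.requires_grad:
                a._accumulate(
                    np.einsum(f"{out_spec},{sb}->{sa}", g, b.data, optimize=True)
                )
            if b.requires_grad:
                b._accumulate(
                    np.einsum(f"{out_spec},{sa}->{sb}", g, a.data, optimize=True)
                )
        out._backward = bwd
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Valid (un-padded) 1-D convolution over the last axis.

    ``x``: (B, C, P); ``w``: (O, C, K); ``b``: (O,) -> (B, O, P_out) with
    ``P_out = (P - K) // stride + 1``.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    B, C, P = x.shape
    O, Cw, K = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {Cw}")
    if P < K:
        raise ValueError(f"input length {P} shorter than kernel {K}")
    p_out = (P - K) // stride + 1
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)[:, :, ::stride, :]
    val = np.einsum("ock,bcpk->bop", w.data, cols, optimize=True) + b.data[None, :, None]
    out = _node(val, (x, w, b))
    if out.requires_grad:
        def bwd(g):
            if w.requires_grad:
                w._accumulate(np.einsum("bop,bcpk->ock", g, cols, optimize=True))
            if b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gx = np.zeros_like(x.data)
                for k in range(K):
                    gx[:, :, k : k + stride * p_out : stride] += np.einsum(
                        "bop,oc->bcp", g, w.data[:, :, k], optimize=True
                    )
                x._accumulate(gx)
        out._backward = bwd
    return out


class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot_uniform(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)
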