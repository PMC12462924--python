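"""Minimal reverse-mode automatic differentiation on numpy arrays.

The training stages in this package need three things from a tensor library:
ordinary layer gradients, a gradient-reversal node with a custom backward rule,
and bitwise-reproducible CPU execution.  This module provides exactly that: a
:class:`Tensor` wrapping an ``ndarray``, a closed set of differentiable
operations, and an Adam optimizer.  Graphs are built eagerly; calling
``backward()`` on a scalar runs a topological sweep accumulating ``grad``.

Broadcasting follows numpy semantics; gradients flowing into a broadcast
operand are summed over the broadcast axes (``_unbroadcast``).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DTYPE",
    "set_default_dtype",
    "default_dtype",
    "Tensor",
    "as_tensor",
    "concatenate",
    "stack",
    "maximum",
    "grad_reversal",
    "sigmoid",
    "silu",
    "relu",
    "softmax",
    "log_softmax",
    "Adam",
    "numerical_grad",
]


DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    """Set the float precision for new tensors.

    float64 (the default) is used for gradient checks and oracle tests;
    float32 halves memory traffic and is the precision the training loops
    run at.
    """
    global DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be numpy float32 or float64")
    DTYPE = dtype


@contextlib.contextmanager
def default_dtype(dtype):
    prev = DTYPE
    set_default_dtype(dtype)
    try:
        yield
    finally:
        set_default_dtype(prev)


class Tensor:
    """A node in the computation graph holding a floating-point array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "_push")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # topological order by depth-first post-order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(order):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            node._push = lambda parent, pg, grads=grads: _accumulate(grads, parent, pg)
            node._backward(g)
            del node._push
        # leaves without _backward already handled above

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = self._make(self.data + other.data, (self, other), None)
        out._backward = _binary_backward(out, self, other,
                                         lambda g: g, lambda g: g)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = self._make(-self.data, (self,), None)
        out._backward = _unary_backward(out, self, lambda g: -g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = self._make(self.data * other.data, (self, other), None)
        out._backward = _binary_backward(out, self, other,
                                         lambda g: g * other.data,
                                         lambda g: g * self.data)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = self._make(self.data / other.data, (self, other), None)
        out._backward = _binary_backward(
            out, self, other,
            lambda g: g / other.data,
            lambda g: -g * self.data / (other.data ** 2))
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not isinstance(exponent, (int, float)):
            raise TypeError("only scalar exponents are supported")
        out = self._make(self.data ** exponent, (self,), None)
        out._backward = _unary_backward(
            out, self, lambda g: g * exponent * self.data ** (exponent - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self._make(np.matmul(self.data, other.data), (self, other), None)

        def grad_a(g):
            if other.data.ndim == 1:
                return np.multiply.outer(g, other.data) if self.data.ndim > 1 else g * other.data
            return np.matmul(g, np.swapaxes(other.data, -1, -2))

        def grad_b(g):
            if self.data.ndim == 1:
                return np.multiply.outer(self.data, g) if other.data.ndim > 1 else self.data * g
            return np.matmul(np.swapaxes(self.data, -1, -2), g)

        out._backward = _binary_backward(out, self, other, grad_a, grad_b)
        return out

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        data = np.exp(self.data)
        out = self._make(data, (self,), None)
        out._backward = _unary_backward(out, self, lambda g: g * data)
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        out._backward = _unary_backward(out, self, lambda g: g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        data = np.tanh(self.data)
        out = self._make(data, (self,), None)
        out._backward = _unary_backward(out, self, lambda g: g * (1.0 - data ** 2))
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        out = self._make(data, (self,), None)
        out._backward = _unary_backward(out, self, grad_fn)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis: int, keepdims: bool = False):
        data = self.data.max(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            expanded = data if keepdims else np.expand_dims(data, axis)
            mask = (self.data == expanded)
            # split gradient evenly across ties for symmetry
            counts = mask.sum(axis=axis, keepdims=True)
            gg = g if keepdims else np.expand_dims(g, axis)
            return mask * (gg / counts)

        out = self._make(data, (self,), None)
        out._backward = _unary_backward(out, self, grad_fn)
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = self._make(self.data.reshape(shape), (self,), None)
        out._backward = _unary_backward(out, self,
                                        lambda g: g.reshape(self.data.shape))
        return out

    def swapaxes(self, a: int, b: int):
        out = self._make(np.swapaxes(self.data, a, b), (self,), None)
        out._backward = _unary_backward(out, self, lambda g: np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        data = self.data[idx]
        idx_tuple = idx if isinstance(idx, tuple) else (idx,)
        # basic (slice/int) indexing never aliases, so += beats np.add.at
        basic = all(isinstance(i, (slice, int)) for i in idx_tuple)

        def grad_fn(g):
            full = np.zeros_like(self.data)
            if basic:
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            return full

        out = self._make(data, (self,), None)
        out._backward = _unary_backward(out, self, grad_fn)
        return out

def _accumulate(grads: dict, parent: Tensor, g: np.ndarray) -> None:
    if not parent.requires_grad:
        return
    key = id(parent)
    if key in grads:
        grads[key] = grads[key] + g
    else:
        grads[key] = g


def _unary_backward(out: Tensor, a: Tensor, fn: Callable):
    def backward(g):
        if a.requires_grad:
            out._push(a, fn(g))
    return backward


def _binary_backward(out: Tensor, a: Tensor, b: Tensor,
                     fa: Callable, fb: Callable):
    def backward(g):
        if a.requires_grad:
            out._push(a, _unbroadcast(fa(g), a.data.shape))
        if b.requires_grad:
            out._push(b, _unbroadcast(fb(g), b.data.shape))
    return backward


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    out._push(t, g[tuple(sl)])
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    out._push(t, np.take(g, i, axis=axis))
        out._backward = backward
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; on ties the gradient is split evenly."""
    a, b = as_tensor(a), as_tensor(b)
    data = np.maximum(a.data, b.data)
    out = Tensor(data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)

        def backward(g):
            tie = (a.data == b.data)
            wa = np.where(a.data > b.data, 1.0, np.where(tie, 0.5, 0.0))
            if a.requires_grad:
                out._push(a, _unbroadcast(g * wa, a.data.shape))
            if b.requires_grad:
                out._push(b, _unbroadcast(g * (1.0 - wa), b.data.shape))
        out._backward = backward
    return out


def conv1d_same(x: Tensor, w: Tensor) -> Tensor:
    """Same-padded 1-D convolution: x (B, L, C_in), w (k, C_in, C_out).

    Implemented as one im2col matmul so the whole layer is a single graph
    node; the backward pass scatters the window gradient back with k
    shifted adds.
    """
    k, c_in, c_out = w.shape
    B, L, _ = x.shape
    pad_l, pad_r = (k - 1) // 2, k // 2
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    # (B, L, C_in, k) -> (B, L, k*C_in)
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B, L, k * c_in)
    w2 = w.data.reshape(k * c_in, c_out)
    out = Tensor(win @ w2)
    if x.requires_grad or w.requires_grad:
        out.requires_grad = True
        out._parents = (x, w)

        def backward(g):
            if w.requires_grad:
                gw = win.reshape(-1, k * c_in).T @ g.reshape(-1, c_out)
                out._push(w, gw.reshape(k, c_in, c_out))
            if x.requires_grad:
                dwin = (g @ w2.T).reshape(B, L, k, c_in)
                dxp = np.zeros_like(xp)
                for j in range(k):
                    dxp[:, j:j + L] += dwin[:, :, j]
                out._push(x, dxp[:, pad_l:pad_l + L])
        out._backward = backward
    return out


def grad_reversal(x: Tensor, lam: float) -> Tensor:
    """Identity in the forward pass; backward multiplies the gradient by -lam.

    The forward output shares the input's array, so the identity holds
    bit-for-bit.  ``lam`` >= 0 controls the strength of the reversed signal
    reaching upstream parameters during adversarial training.
    """
    if lam < 0:
        raise ValueError("gradient-reversal strength must be >= 0")
    out = Tensor(x.data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def backward(g):
            out._push(x, -lam * g)
        out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    with np.errstate(over="ignore"):  # exp overflow saturates correctly
        data = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = _unary_backward(out, x, lambda g: g * data * (1.0 - data))
    return out


def silu(x: Tensor) -> Tensor:
    """SiLU (swish) activation x * sigmoid(x)."""
    x = as_tensor(x)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-x.data))
    data = x.data * s
    out = Tensor(data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = _unary_backward(out, x,
                                        lambda g: g * (s * (1.0 + x.data * (1.0 - s))))
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    data = np.maximum(x.data, 0.0)
    out = Tensor(data)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = _unary_backward(out, x, lambda g: g * (x.data > 0))
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max(axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


class Adam:
    """Adam optimizer over a list of parameter tensors.

    Moment accumulators are kept in float64 regardless of the model
    precision; with float32 parameters the tiny squared-gradient moments
    otherwise lose enough precision to degrade convergence.
    """

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros(p.data.shape) for p in self.params]
        self.v = [np.zeros(p.data.shape) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = np.asarray(p.grad, dtype=np.float64)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data -= (self.lr * self.weight_decay) * p.data
            p.data -= (self.lr * mh / (np.sqrt(vh) + self.eps)).astype(
                p.data.dtype)


def numerical_grad(fn: Callable[[np.ndarray], float], x: np.ndarray,
                   eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of a scalar function, for tests."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        f_plus = fn(x)
        x[i] = orig - eps
        f_minus = fn(x)
        x[i] = orig
        g[i] = (f_plus - f_minus) / (2 * eps)
        it.iternext()
    return g
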