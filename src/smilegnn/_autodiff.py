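"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the handful of operations the pair-scoring network needs are
implemented: broadcasting arithmetic, row gathering from embedding
tables, batched linear maps, tanh/relu/softmax, reductions, and a
numerically stable binary cross-entropy on logits.  Gradients are
accumulated by topological-order traversal of the operation graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "concat", "softmax", "bce_with_logits", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def matmul(self, w: "Tensor") -> "Tensor":
        """Batched `x @ W` with a 2-D weight `W`; leading axes of x kept."""
        w = self._coerce(w)
        if w.ndim != 2:
            raise ValueError("matmul weight must be 2-D")
        x2 = self.data.reshape(-1, self.data.shape[-1])
        out = (x2 @ w.data).reshape(self.data.shape[:-1] + (w.data.shape[1],))

        def bwd(g):
            g2 = g.reshape(-1, g.shape[-1])
            if self.requires_grad:
                self._accumulate((g2 @ w.data.T).reshape(self.data.shape))
            if w.requires_grad:
                w._accumulate(x2.T @ g2)

        return Tensor(out, parents=(self, w), backward=bwd)

    __matmul__ = matmul

    # -- shaping -------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        return Tensor(self.data.reshape(shape), parents=(self,), backward=bwd)

    def take(self, idx) -> "Tensor":
        """Gather rows; backward scatter-adds into the source table."""
        idx = np.asarray(idx)

        def bwd(g):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, idx, g)
                self._accumulate(acc)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    def expand_dims(self, axis: int) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accumulate(np.squeeze(g, axis=axis))

        return Tensor(np.expand_dims(self.data, axis), parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis=axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out, parents=(self,), backward=bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ------------------------------------------------
    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out * out))

        return Tensor(out, parents=(self,), backward=bwd)

    def relu(self) -> "Tensor":
        out = np.maximum(self.data, 0.0)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0.0))

        return Tensor(out, parents=(self,), backward=bwd)

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=bwd)


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=bwd)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    z = t.data - t.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if t.requires_grad:
            inner = (g * out).sum(axis=axis, keepdims=True)
            t._accumulate(out * (g - inner))

    return Tensor(out, parents=(t,), backward=bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray, reduction: str = "mean") -> Tensor:
    """Binary cross-entropy on raw scores, stable for large |logits|."""
    y = np.asarray(targets, dtype=np.float64)
    z = logits.data
    # log(1 + e^{-|z|}) + max(z, 0) - z*y, the standard stable form
    losses = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y
    if reduction == "mean":
        out, scale = losses.mean(), 1.0 / y.size
    elif reduction == "sum":
        out, scale = losses.sum(), 1.0
    else:
        raise ValueError(f"unknown reduction {reduction!r}")
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))

    def bwd(g):
        if logits.requires_grad:
            logits._accumulate(g * scale * (p - y))

    return Tensor(out, parents=(logits,), backward=bwd)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
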