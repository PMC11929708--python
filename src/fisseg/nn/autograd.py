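"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operator set needed by the point-cloud
networks in this package: broadcasting elementwise arithmetic, (batched)
matmul, reductions, gather/scatter indexing, concatenation and the usual
activation functions.  Tensors are channels-last; float32 is the working
precision.

Gradients are accumulated into ``Tensor.grad`` (a plain ndarray) by
``Tensor.backward()`` via topological traversal of the recorded graph.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording within the context (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    # -- shape helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        return Tensor._make(
            self.data + o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, o.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        return Tensor._make(
            self.data - o.data, (self, o),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, o.shape)))

    def __rsub__(self, other):
        return Tensor(_as_array(other)) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        return Tensor._make(
            self.data * o.data, (self, o),
            lambda g: (_unbroadcast(g * o.data, self.shape),
                       _unbroadcast(g * self.data, o.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        return Tensor._make(
            self.data / o.data, (self, o),
            lambda g: (_unbroadcast(g / o.data, self.shape),
                       _unbroadcast(-g * self.data / (o.data ** 2), o.shape)))

    def __rtruediv__(self, other):
        return Tensor(_as_array(other)) / self

    def __pow__(self, p: float):
        return Tensor._make(
            self.data ** p, (self,),
            lambda g: (g * p * self.data ** (p - 1),))

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(_as_array(other))
        out = np.matmul(self.data, o.data)

        def backward(g):
            a, b = self.data, o.data
            if a.ndim == 1 and b.ndim == 1:
                return g * b, g * a
            if a.ndim == 1:          # (k,) @ (k, m) -> (m,)
                return np.matmul(g, np.swapaxes(b, -1, -2)), np.outer(a, g)
            if b.ndim == 1:          # (..., n, k) @ (k,) -> (..., n)
                ga = g[..., None] * b
                gb = np.matmul(np.swapaxes(a, -1, -2), g[..., None])[..., 0]
                return ga, _unbroadcast(gb, b.shape)
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, o.shape)

        return Tensor._make(out, (self, o), backward)

    # -- unary ---------------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def leaky_relu(self, slope: float = 0.2):
        mult = np.where(self.data > 0, 1.0, slope).astype(np.float32)
        return Tensor._make(self.data * mult, (self,), lambda g: (g * mult,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1 - out ** 2),))

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).astype(np.float32),)

        return Tensor._make(out, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; ties route gradient to the first maximum."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis)
        if not keepdims:
            out = np.squeeze(out, axis)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            gx = np.zeros_like(self.data)
            np.put_along_axis(gx, np.expand_dims(idx, axis), g, axis)
            return (gx,)

        return Tensor._make(out, (self,), backward)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def broadcast_to(self, shape):
        old = self.shape
        return Tensor._make(np.broadcast_to(self.data, shape).copy(), (self,),
                            lambda g: (_unbroadcast(g, old),))

    def __getitem__(self, key):
        out = self.data[key]

        if isinstance(key, np.ndarray) and key.dtype.kind in "iu":
            # row gather: scatter-add backward via a sparse one-hot matmul
            # (np.add.at is orders of magnitude slower at this size)
            from scipy import sparse

            idx = key.ravel()
            shape = self.shape

            def backward(g):
                gf = g.reshape(len(idx), -1)
                onehot = sparse.csr_matrix(
                    (np.ones(len(idx), dtype=np.float32), idx,
                     np.arange(len(idx) + 1)),
                    shape=(len(idx), shape[0]))
                return ((onehot.T @ gf).reshape(shape),)

            return Tensor._make(out, (self,), backward)

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, key, g)
            return (gx,)

        return Tensor._make(out, (self,), backward)


# -- free functions ----------------------------------------------------

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(data, tensors, backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = list(tensors)
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple(np.squeeze(p, axis=axis) for p in parts)

    return Tensor._make(data, tensors, backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x - Tensor(m)  # constant shift; gradient flows through x only
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  weights: np.ndarray | None = None) -> Tensor:
    """Mean cross-entropy over the leading axis, optional per-class weights.

    Weighted form follows the usual convention: sum(w_y * nll) / sum(w_y).
    """
    labels = np.asarray(labels)
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), labels]
    if weights is None:
        return -picked.mean()
    w = np.asarray(weights, dtype=np.float32)[labels]
    denom = max(float(w.sum()), 1e-12)
    return -(picked * Tensor(w)).sum() * (1.0 / denom)
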