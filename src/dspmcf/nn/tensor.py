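"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients into every tensor created with ``requires_grad=True``.
The operation set is exactly what the encoder/decoder networks in this
package need (broadcasted arithmetic, matmul, tanh/sigmoid/relu, exp/log,
reductions, reshaping, concatenation, slicing) — it is not a general array
library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "grad_reversal", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim >= 2 and b.ndim >= 2:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            elif a.ndim >= 2 and b.ndim == 1:
                # (..., m, k) @ (k,) -> (..., m)
                ga = g[..., :, None] * b
                tmp = g[..., :, None] * a
                gb = tmp.reshape(-1, a.shape[-1]).sum(axis=0)
            elif a.ndim == 1 and b.ndim >= 2:
                # (k,) @ (..., k, n) -> (..., n)
                tmp = g[..., None, :] * b  # (..., k, n)
                ga = tmp.sum(axis=-1).reshape(-1, a.shape[0]).sum(axis=0) if tmp.ndim > 2 else tmp.sum(axis=-1)
                gb = a[:, None] * g[..., None, :]
            else:  # 1-D dot product
                ga = g * b
                gb = g * a
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo (used for KL epsilon)."""
        mask = self.data > lo
        return self._make(np.maximum(self.data, lo), (self,), lambda g: (g * mask,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            ax = tuple(a % self.ndim for a in ax)
            if not keepdims:
                for a in sorted(ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)
        return self._make(out_data, (self,), lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- backward pass --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._parents:
                parent_grads = node._backward(g)
                for p, pg in zip(node._parents, parent_grads):
                    if not p.requires_grad or pg is None:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg
            else:
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def grad_reversal(x: Tensor, lam: float) -> Tensor:
    """Gradient reversal: identity forward, gradients scaled by ``-lam``.

    The standard trick for adversarial domain training with a single
    optimizer: the discriminator minimizes its loss while the upstream
    encoder receives the negated (scaled) gradient and therefore maximizes
    it.
    """
    out = Tensor(x.data)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = lambda g: (-lam * g,)
    return out
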