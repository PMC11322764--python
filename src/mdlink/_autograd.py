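"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the attention-GCN and the convolutional
sparse autoencoder need: broadcasting arithmetic, matmul, reshaping and
transposition, basic slicing, zero-padding, elementwise nonlinearities and
axis reductions.  Gradients are accumulated into ``Tensor.grad`` by
``Tensor.backward()`` over a topologically sorted graph.

The engine is deliberately small; correctness is pinned by the
finite-difference gradient checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "_grad_owned")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None
        self._grad_owned = False

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    # -- graph helpers ----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        # The first accumulation stores a (possibly shared) reference; only
        # after a second contribution do we allocate a private buffer.
        if self.grad is None:
            self.grad = grad
            self._grad_owned = False
        elif self._grad_owned:
            self.grad += grad
        else:
            self.grad = self.grad + grad
            self._grad_owned = True

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(a.data**p, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, key):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[key] = g
                a._accum(full)

        return self._make(a.data[key], (a,), backward)

    def pad(self, pad_width):
        """Zero-pad; `pad_width` as for np.pad."""
        a = self
        slices = tuple(
            slice(lo, lo + n) for (lo, _hi), n in zip(pad_width, a.data.shape)
        )

        def backward(g):
            if a.requires_grad:
                a._accum(g[slices])

        return self._make(np.pad(a.data, pad_width), (a,), backward)

    # -- nonlinearities ---------------------------------------------------
    def relu(self):
        a = self
        out_data = np.maximum(a.data, 0)

        def backward(g):
            if a.requires_grad:
                a._accum(g * (a.data > 0))

        return self._make(out_data, (a,), backward)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        pos = a.data > 0
        out_data = np.where(pos, a.data, slope * a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * np.where(pos, 1.0, slope))

        return self._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        # +/-30 saturates to 1 ulp in float32 and avoids exp overflow there
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -30, 30)))

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (a,), backward)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * out_data)

        return self._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(a.data), (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the un-clipped region only."""
        a = self
        inside = (a.data >= lo) & (a.data <= hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * inside)

        return self._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if a.requires_grad:
                if axis is None:
                    a._accum(np.broadcast_to(g, a.data.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- backprop ---------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(lo, hi)
                    t._accum(g[tuple(idx)])

        out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
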