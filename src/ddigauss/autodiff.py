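"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for the two classifier graphs in this package:
broadcast-aware arithmetic, matmul (batched), tanh, softmax, max-reduction,
slicing/gather, concat/reshape/transpose and a fused softmax
cross-entropy.  Gradients accumulate into ``Tensor.grad`` after
``backward()`` on a scalar.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- niceties ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# primitive ops


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def bw(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def bw(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        _accumulate(a, _unbroadcast(ga, a.data.shape))
        _accumulate(b, _unbroadcast(gb, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bw)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)

    def bw(g):
        _accumulate(a, g * (1.0 - y * y))

    return Tensor(y, parents=(a,), backward=bw)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        _accumulate(a, g.reshape(a.data.shape))

    return Tensor(a.data.reshape(shape), parents=(a,), backward=bw)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)

    def bw(g):
        _accumulate(a, g.transpose(inv))

    return Tensor(a.data.transpose(axes), parents=(a,), backward=bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                  parents=tuple(tensors), backward=bw)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            _accumulate(a, full)

    return Tensor(a.data[idx], parents=(a,), backward=bw)


def take_rows(table, indices) -> Tensor:
    """Embedding lookup: gather rows of a 2-D table by an integer array."""
    table = as_tensor(table)
    indices = np.asarray(indices)

    def bw(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, indices.reshape(-1),
                      g.reshape(-1, table.data.shape[-1]))
            _accumulate(table, full)

    return Tensor(table.data[indices], parents=(table,), backward=bw)


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return Tensor(out_data, parents=(a,), backward=bw)


def mean_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in np.atleast_1d(axis)]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def amax(a, axis: int) -> Tensor:
    """Max-reduction; gradient flows to the (first) argmax positions."""
    a = as_tensor(a)
    out_data = a.data.max(axis=axis)
    arg = a.data.argmax(axis=axis)

    def bw(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.put_along_axis(
                full, np.expand_dims(arg, axis),
                np.expand_dims(g, axis), axis=axis,
            )
            _accumulate(a, full)

    return Tensor(out_data, parents=(a,), backward=bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accumulate(a, y * (g - dot))

    return Tensor(y, parents=(a,), backward=bw)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer class labels (fused grad)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = -logp[np.arange(n), labels].mean()

    def bw(g):
        p = np.exp(logp)
        p[np.arange(n), labels] -= 1.0
        _accumulate(logits, g * p / n)

    return Tensor(loss, parents=(logits,), backward=bw)


def dropout(a, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity (same object) when not training or rate 0."""
    a = as_tensor(a)
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep) / keep
    return mul(a, Tensor(mask))


# ---------------------------------------------------------------------------
# parameter helpers


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


def glorot(rng: np.random.Generator, shape: tuple) -> Tensor:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return parameter(rng.uniform(-limit, limit, size=shape))


def zeros(shape) -> Tensor:
    return parameter(np.zeros(shape))


def sliding_windows(x: Tensor, h: int, axis: int) -> Tensor:
    """Concatenate ``h`` shifted slices along the last axis.

    For input (..., L, W) returns (..., L-h+1, h*W): window *i* holds rows
    ``i .. i+h-1`` flattened — the im2col view a convolution filter dots.
    """
    L = x.shape[axis]
    P = L - h + 1
    if P < 1:
        raise ValueError(f"sequence length {L} shorter than window {h}")
    slicer = [slice(None)] * len(x.shape)
    pieces = []
    for i in range(h):
        s = list(slicer)
        s[axis] = slice(i, i + P)
        pieces.append(getitem(x, tuple(s)))
    return concat(pieces, axis=-1)
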