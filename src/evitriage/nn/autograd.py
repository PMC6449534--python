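"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations needed by the text classifiers live here: affine maps,
pointwise nonlinearities, slicing/concatenation, max/sum reductions, masked
softmax, embedding lookup and a fused softmax cross-entropy. Everything is
dense float64 numpy; determinism follows from single-threaded numpy ops.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "tensor", "add", "mul", "matmul", "tanh", "sigmoid", "relu",
    "slice_axis", "concat", "max_axis", "sum_axis", "mean_all", "reshape",
    "transpose_last2", "embedding_lookup", "masked_softmax",
    "softmax_cross_entropy", "dropout_mask", "flip_axis",
]


class Tensor:
    """A node in the computation graph: an ndarray plus gradient plumbing."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "is_weight")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Accumulate gradients through the graph rooted at this tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """a @ b; supports (..., m, k) @ (k, n) and (m, k) @ (k, n)."""
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T if b.data.ndim == 2 else g @ np.swapaxes(b.data, -1, -2))
        if b.requires_grad:
            if a.data.ndim == 2:
                b._accumulate(a.data.T @ g)
            else:
                ga = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(ga.reshape(-1, *ga.shape[-2:]).sum(axis=0) if ga.ndim > 2 else ga)

    return Tensor(out_data, parents=(a, b), backward=backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - out_data ** 2))

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    out_data = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * (x.data > 0.0))

    return Tensor(out_data, parents=(x,), backward=backward)


def slice_axis(x: Tensor, axis: int, start: int, stop: int) -> Tensor:
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, stop)
    idx = tuple(idx)
    out_data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accumulate(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(parts: list[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                p._accumulate(g[tuple(idx)])

    return Tensor(out_data, parents=tuple(parts), backward=backward)


def max_axis(x: Tensor, axis: int) -> Tensor:
    """Max over one axis; gradient routed to the (first) argmax position."""
    out_data = x.data.max(axis=axis)
    arg = np.expand_dims(x.data.argmax(axis=axis), axis)

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.put_along_axis(full, arg, np.expand_dims(g, axis), axis=axis)
            x._accumulate(full)

    return Tensor(out_data, parents=(x,), backward=backward)


def sum_axis(x: Tensor, axis: int) -> Tensor:
    out_data = x.data.sum(axis=axis)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.broadcast_to(np.expand_dims(g, axis), x.data.shape).copy())

    return Tensor(out_data, parents=(x,), backward=backward)


def mean_all(x: Tensor) -> Tensor:
    n = x.data.size
    out_data = np.asarray(x.data.mean())

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, g / n))

    return Tensor(out_data, parents=(x,), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    return Tensor(out_data, parents=(x,), backward=backward)


def transpose_last2(x: Tensor) -> Tensor:
    out_data = np.swapaxes(x.data, -1, -2)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.swapaxes(g, -1, -2))

    return Tensor(out_data, parents=(x,), backward=backward)


def flip_axis(x: Tensor, axis: int) -> Tensor:
    out_data = np.flip(x.data, axis=axis)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.flip(g, axis=axis))

    return Tensor(out_data, parents=(x,), backward=backward)


def embedding_lookup(table: Tensor, ids: np.ndarray) -> Tensor:
    """Gather rows of `table` (|V| x d) by integer ids of any shape."""
    ids = np.asarray(ids, dtype=np.int64)
    out_data = table.data[ids]

    def backward(g):
        if table.requires_grad:
            grad = np.zeros_like(table.data)
            np.add.at(grad, ids.ravel(), g.reshape(-1, table.data.shape[1]))
            table._accumulate(grad)

    return Tensor(out_data, parents=(table,), backward=backward)


def masked_softmax(scores: Tensor, mask: np.ndarray | None = None,
                   axis: int = -1) -> Tensor:
    """Softmax along `axis`; positions where mask==0 get zero weight."""
    s = scores.data
    if mask is not None:
        s = np.where(mask.astype(bool), s, -np.inf)
    s = s - s.max(axis=axis, keepdims=True)
    e = np.exp(s)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if scores.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            scores._accumulate(out_data * (g - dot))

    return Tensor(out_data, parents=(scores,), backward=backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                          sample_weight: np.ndarray | None = None):
    """(Weighted) mean cross-entropy of softmax(logits) vs integer labels.

    Returns (loss Tensor, probabilities ndarray). With ``sample_weight``
    the loss is sum(w_i * nll_i) / sum(w).
    """
    labels = np.asarray(labels, dtype=np.int64)
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=-1, keepdims=True)
    n = labels.shape[0]
    nll = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None))
    if sample_weight is None:
        w = np.full(n, 1.0 / n)
    else:
        sw = np.asarray(sample_weight, dtype=np.float64)
        w = sw / sw.sum()
    loss_data = np.asarray((w * nll).sum())

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad * w[:, None])

    return Tensor(loss_data, parents=(logits,), backward=backward), probs


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with probability `rate`, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = rng.random(shape) >= rate
    return keep / (1.0 - rate)
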