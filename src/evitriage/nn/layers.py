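"""Network building blocks: dense, 1-D convolution, (Bi)LSTM, attention pooling.

Parameters are plain :class:`~evitriage.nn.autograd.Tensor` objects; layers
expose ``params()`` so optimizers and serialization can reach them. Weight
matrices carry ``is_weight=True`` metadata used for L2 regularization.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def glorot(shape, rng: np.random.Generator) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def make_param(data, is_weight: bool = True) -> Tensor:
    t = Tensor(data, requires_grad=True)
    t.is_weight = is_weight  # type: ignore[attr-defined]
    return t


class Layer:
    def params(self) -> list[Tensor]:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.W = make_param(glorot((in_dim, out_dim), rng))
        self.b = make_param(np.zeros(out_dim), is_weight=False)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        y = ag.add(ag.matmul(x, self.W), self.b)
        if self.activation == "relu":
            y = ag.relu(y)
        elif self.activation == "tanh":
            y = ag.tanh(y)
        return y

    def params(self):
        return [self.W, self.b]


class Conv1D(Layer):
    """Valid 1-D convolution over the token axis of a (B, T, d) input.

    Implemented as a sum of shifted affine maps, one per filter tap, which
    keeps the whole computation inside the autodiff graph.
    """

    def __init__(self, in_dim: int, filters: int, width: int,
                 rng: np.random.Generator, activation: str = "relu"):
        self.width = width
        self.filters = filters
        self.taps = [make_param(glorot((in_dim, filters), rng)) for _ in range(width)]
        self.b = make_param(np.zeros(filters), is_weight=False)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        if T < self.width:
            raise ValueError(
                f"sequence length {T} shorter than filter width {self.width}")
        out_len = T - self.width + 1
        y = ag.add(ag.matmul(ag.slice_axis(x, 1, 0, out_len), self.taps[0]), self.b)
        for k in range(1, self.width):
            y = ag.add(y, ag.matmul(ag.slice_axis(x, 1, k, k + out_len), self.taps[k]))
        if self.activation == "relu":
            y = ag.relu(y)
        return y

    def params(self):
        return [*self.taps, self.b]


class ConvMaxPool(Layer):
    """Parallel convolutions of several widths, each globally max-pooled."""

    def __init__(self, in_dim: int, filters: int, widths: tuple[int, ...],
                 rng: np.random.Generator):
        self.convs = [Conv1D(in_dim, filters, w, rng) for w in widths]
        self.out_dim = filters * len(widths)

    def __call__(self, x: Tensor) -> Tensor:
        pooled = [ag.max_axis(conv(x), axis=1) for conv in self.convs]
        return pooled[0] if len(pooled) == 1 else ag.concat(pooled, axis=-1)

    def params(self):
        return [p for c in self.convs for p in c.params()]


class LSTM(Layer):
    """Standard LSTM; returns the final hidden state (B, units)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.units = units
        self.Wx = make_param(glorot((in_dim, 4 * units), rng))
        self.Wh = make_param(glorot((units, 4 * units), rng))
        b = np.zeros(4 * units)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.b = make_param(b, is_weight=False)

    def __call__(self, x: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        """Run over (B, T, d); with ``lengths`` the state at each sequence's
        last real token is returned instead of the state at T-1, so tail
        padding cannot wash out the memory."""
        B, T, _ = x.shape
        u = self.units
        h = Tensor(np.zeros((B, u)))
        c = Tensor(np.zeros((B, u)))
        h_sel = Tensor(np.zeros((B, u))) if lengths is not None else None
        for t in range(T):
            xt = ag.reshape(ag.slice_axis(x, 1, t, t + 1), (B, x.shape[2]))
            z = ag.add(ag.add(ag.matmul(xt, self.Wx), ag.matmul(h, self.Wh)), self.b)
            i = ag.sigmoid(ag.slice_axis(z, 1, 0, u))
            f = ag.sigmoid(ag.slice_axis(z, 1, u, 2 * u))
            g = ag.tanh(ag.slice_axis(z, 1, 2 * u, 3 * u))
            o = ag.sigmoid(ag.slice_axis(z, 1, 3 * u, 4 * u))
            c = ag.add(ag.mul(f, c), ag.mul(i, g))
            h = ag.mul(o, ag.tanh(c))
            if lengths is not None:
                pick = (np.maximum(lengths, 1) - 1 == t).astype(float)[:, None]
                if pick.any():
                    h_sel = ag.add(h_sel, ag.mul(h, Tensor(pick)))
        return h_sel if lengths is not None else h

    def params(self):
        return [self.Wx, self.Wh, self.b]


class BiLSTM(Layer):
    """Forward + time-reversed LSTM; concatenated final states (B, 2*units)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        self.fwd = LSTM(in_dim, units, rng)
        self.bwd = LSTM(in_dim, units, rng)
        self.out_dim = 2 * units

    def __call__(self, x: Tensor, lengths: np.ndarray | None = None) -> Tensor:
        # the reversed pass ends on each sequence's first token, so only the
        # forward pass needs masked final-state selection
        return ag.concat([self.fwd(x, lengths),
                          self.bwd(ag.flip_axis(x, 1))], axis=-1)

    def params(self):
        return self.fwd.params() + self.bwd.params()


class AttentionPool(Layer):
    """Additive (single-layer) attention over a (B, P, E) stack of vectors.

    score_i = v^T tanh(W h_i + b); weights = softmax over passages;
    output = sum_i weight_i * h_i. Position-free by construction.
    """

    def __init__(self, in_dim: int, width: int, rng: np.random.Generator):
        self.W = make_param(glorot((in_dim, width), rng))
        self.b = make_param(np.zeros(width), is_weight=False)
        self.v = make_param(glorot((width, 1), rng))

    def __call__(self, H: Tensor, mask: np.ndarray | None = None):
        """Returns (weights Tensor (B, P), pooled Tensor (B, E))."""
        proj = ag.tanh(ag.add(ag.matmul(H, self.W), self.b))
        scores = ag.reshape(ag.matmul(proj, self.v), H.shape[:2])
        weights = ag.masked_softmax(scores, mask=mask, axis=-1)
        w3 = ag.reshape(weights, (*weights.shape, 1))
        pooled = ag.sum_axis(ag.mul(H, w3), axis=1)
        return weights, pooled

    def params(self):
        return [self.W, self.b, self.v]


class MeanPool(Layer):
    """Masked mean over passages — the ablation baseline for attention."""

    def __call__(self, H: Tensor, mask: np.ndarray | None = None):
        B, P, _ = H.shape
        if mask is None:
            w = np.full((B, P), 1.0 / P)
        else:
            m = mask.astype(float)
            w = m / m.sum(axis=1, keepdims=True)
        weights = Tensor(w)
        w3 = ag.reshape(weights, (B, P, 1))
        pooled = ag.sum_axis(ag.mul(H, w3), axis=1)
        return weights, pooled

    def params(self):
        return []


class Adam:
    """Adam with optional L2 penalty applied to weight-flagged parameters."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.l2 and getattr(p, "is_weight", False):
                g = g + 2.0 * self.l2 * p.data
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1 ** self.t)
            vhat = self.v[i] / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
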