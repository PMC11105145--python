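"""Minimal reverse-mode autodiff and recurrent layers on numpy.

This is a compact, self-contained neural-network core sized for
sentence-level classifiers at desk scale: 2-D tensors, a handful of
primitives, GRU/LSTM cells run bidirectionally over padded token batches,
additive attention pooling, and Adam.  Everything is seeded through numpy
Generators, and all computation is plain float32 numpy, so identical
seeds/config/data give identical parameters and predictions.

Conventions: batches are ``(B, D)`` matrices; a sentence batch is a list of
``(B, D)`` embedding matrices, one per time step, plus a ``(B, T)`` 0/1 mask.
Padded positions carry the previous hidden state through unchanged.
"""

from __future__ import annotations

from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

Array = np.ndarray
_f32 = np.float32


def _as_array(x) -> Array:
    return np.asarray(x, dtype=_f32)


def _unbroadcast(grad: Array, shape: Tuple[int, ...]) -> Array:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an accumulated gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(
        self,
        data,
        parents: Tuple["Tensor", ...] = (),
        backward: Optional[Callable[[Array], None]] = None,
        requires_grad: bool = False,
    ):
        self.data = _as_array(data)
        self.grad: Optional[Array] = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = g.astype(_f32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    return Tensor(data, requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def _coerce(x: Union[Tensor, float, int, Array]) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitives


def add(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    out._backward = bw
    return out


def mul(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    out._backward = bw
    return out


def sub(a, b) -> Tensor:
    return add(a, mul(b, -1.0))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bw(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, parents=(x,))

    def bw(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))

    def bw(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))

    out._backward = bw
    return out


def concat_cols(parts: Sequence[Tensor]) -> Tensor:
    out = Tensor(np.concatenate([p.data for p in parts], axis=1), parents=tuple(parts))
    widths = [p.data.shape[1] for p in parts]

    def bw(g: Array) -> None:
        off = 0
        for p, w in zip(parts, widths):
            if p.requires_grad:
                p._accumulate(g[:, off : off + w])
            off += w

    out._backward = bw
    return out


def slice_cols(x: Tensor, start: int, stop: int) -> Tensor:
    out = Tensor(x.data[:, start:stop], parents=(x,))

    def bw(g: Array) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, start:stop] = g
            x._accumulate(full)

    out._backward = bw
    return out


def masked_softmax(scores: Tensor, mask: Array) -> Tensor:
    """Row-wise softmax over columns; masked (0) positions get zero weight."""
    z = scores.data + (mask - 1.0) * 1e9
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z) * mask
    denom = e.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    alpha = e / denom
    out = Tensor(alpha, parents=(scores,))

    def bw(g: Array) -> None:
        if scores.requires_grad:
            dot = (g * alpha).sum(axis=1, keepdims=True)
            scores._accumulate(alpha * (g - dot))

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, targets: Array, weight: Optional[Array] = None) -> Tensor:
    """Mean binary cross-entropy from logits (numerically stable)."""
    z, y = logits.data, _as_array(targets)
    w = np.ones_like(z) if weight is None else _as_array(weight)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    denom = max(w.sum(), 1.0)
    out = Tensor(np.array((loss * w).sum() / denom, dtype=_f32), parents=(logits,))

    def bw(g: Array) -> None:
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(g * w * (s - y) / denom)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# layers


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Array:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(_f32)


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 activation: Optional[str] = None):
        self.W = Tensor(glorot(rng, n_in, n_out), requires_grad=True)
        self.b = Tensor(np.zeros((1, n_out), dtype=_f32), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        out = add(matmul(x, self.W), self.b)
        if self.activation == "tanh":
            return tanh(out)
        if self.activation == "sigmoid":
            return sigmoid(out)
        return out

    @property
    def params(self) -> List[Tensor]:
        return [self.W, self.b]


class GRUCell:
    """Standard gated recurrent unit (update z, reset r, candidate n)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        h = n_hidden
        self.h = h
        self.Wx = Tensor(glorot(rng, n_in, 3 * h), requires_grad=True)
        self.Wh_zr = Tensor(glorot(rng, h, 2 * h), requires_grad=True)
        self.Wh_n = Tensor(glorot(rng, h, h), requires_grad=True)
        self.b = Tensor(np.zeros((1, 3 * h), dtype=_f32), requires_grad=True)

    def step(self, x: Tensor, h_prev: Tensor) -> Tensor:
        H = self.h
        gx = add(matmul(x, self.Wx), self.b)
        gh = matmul(h_prev, self.Wh_zr)
        z = sigmoid(add(slice_cols(gx, 0, H), slice_cols(gh, 0, H)))
        r = sigmoid(add(slice_cols(gx, H, 2 * H), slice_cols(gh, H, 2 * H)))
        n = tanh(add(slice_cols(gx, 2 * H, 3 * H), matmul(mul(r, h_prev), self.Wh_n)))
        return add(mul(sub(constant(np.ones((1, H), dtype=_f32)), z), h_prev), mul(z, n))

    @property
    def params(self) -> List[Tensor]:
        return [self.Wx, self.Wh_zr, self.Wh_n, self.b]


class LSTMCell:
    """Standard LSTM (input i, forget f, output o, candidate g)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_hidden: int):
        h = n_hidden
        self.h = h
        self.Wx = Tensor(glorot(rng, n_in, 4 * h), requires_grad=True)
        self.Wh = Tensor(glorot(rng, h, 4 * h), requires_grad=True)
        b = np.zeros((1, 4 * h), dtype=_f32)
        b[:, h : 2 * h] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def step(self, x: Tensor, state: Tuple[Tensor, Tensor]) -> Tuple[Tensor, Tensor]:
        h_prev, c_prev = state
        H = self.h
        g = add(add(matmul(x, self.Wx), matmul(h_prev, self.Wh)), self.b)
        i = sigmoid(slice_cols(g, 0, H))
        f = sigmoid(slice_cols(g, H, 2 * H))
        o = sigmoid(slice_cols(g, 2 * H, 3 * H))
        cand = tanh(slice_cols(g, 3 * H, 4 * H))
        c = add(mul(f, c_prev), mul(i, cand))
        return mul(o, tanh(c)), c

    @property
    def params(self) -> List[Tensor]:
        return [self.Wx, self.Wh, self.b]


def _masked_carry(h_new: Tensor, h_prev: Tensor, m_col: Array) -> Tensor:
    m = constant(m_col)
    inv = constant(1.0 - m_col)
    return add(mul(m, h_new), mul(inv, h_prev))


class BiRecurrent:
    """Runs a cell type over a padded batch in both directions.

    ``cell_kind`` is ``"gru"`` or ``"lstm"``.  Returns the per-timestep
    concatenated hidden states ``[(B, 2H), ...]`` and the final states of
    both directions ``(B, 2H)``.
    """

    def __init__(self, rng: np.random.Generator, cell_kind: str, n_in: int, n_hidden: int):
        cls = {"gru": GRUCell, "lstm": LSTMCell}[cell_kind]
        self.kind = cell_kind
        self.h = n_hidden
        self.fwd = cls(rng, n_in, n_hidden)
        self.bwd = cls(rng, n_in, n_hidden)

    def _run(self, cell, xs: List[Tensor], mask: Array) -> List[Tensor]:
        B = xs[0].shape[0]
        h = constant(np.zeros((B, self.h), dtype=_f32))
        if self.kind == "lstm":
            c = constant(np.zeros((B, self.h), dtype=_f32))
        out = []
        for t, x in enumerate(xs):
            m = mask[:, t : t + 1]
            if self.kind == "lstm":
                h_new, c_new = cell.step(x, (h, c))
                c = _masked_carry(c_new, c, m)
            else:
                h_new = cell.step(x, h)
            h = _masked_carry(h_new, h, m)
            out.append(h)
        return out

    def __call__(self, xs: List[Tensor], mask: Array) -> Tuple[List[Tensor], Tensor]:
        fwd_states = self._run(self.fwd, xs, mask)
        bwd_states = self._run(self.bwd, xs[::-1], mask[:, ::-1])[::-1]
        per_step = [concat_cols([f, b]) for f, b in zip(fwd_states, bwd_states)]
        final = concat_cols([fwd_states[-1], bwd_states[0]])
        return per_step, final

    @property
    def params(self) -> List[Tensor]:
        return self.fwd.params + self.bwd.params


class AttentionPool:
    """Additive attention over time: softmax(v . tanh(W h_t)) weights."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_attn: int):
        self.proj = Dense(rng, n_in, n_attn, activation="tanh")
        self.v = Dense(rng, n_attn, 1)

    def __call__(self, states: List[Tensor], mask: Array) -> Tensor:
        scores = concat_cols([self.v(self.proj(h)) for h in states])  # (B, T)
        alpha = masked_softmax(scores, mask)
        ctx: Optional[Tensor] = None
        for t, h in enumerate(states):
            term = mul(slice_cols(alpha, t, t + 1), h)
            ctx = term if ctx is None else add(ctx, term)
        return ctx

    @property
    def params(self) -> List[Tensor]:
        return self.proj.params + self.v.params


class Adam:
    """Adam optimizer with the usual bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

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
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_f32)
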