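"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package's two trainable stages (the relational graph-convolutional
encoder and the squeeze-and-excitation CNN classifier) are small enough
that full-batch / mini-batch dense numpy math is fast on one CPU core;
this module supplies the gradient machinery they share: a `Tensor` value
wrapper recording a tape of operations, backward rules for the handful
of ops the models need, and an Adam optimizer.

Every op's gradient is exercised by finite-difference checks in the test
suite; new ops must ship with such a check.
"""

from __future__ import annotations

import numpy as np


def _expit(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the closure needed to backpropagate into it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def param(data) -> "Tensor":
        return Tensor(np.array(data, dtype=float), requires_grad=True)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd plumbing ----------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape), dtype=float)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs here can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # -- ops ------------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data)
        out._prev = (self, other)

        def _bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data)
        out._prev = (self, other)

        def _bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data)
        out._prev = (self, other)
        a, b = self.data, other.data

        def _bw(g):
            if a.ndim == 1 and b.ndim == 2:
                self._accum(g @ b.T)
                other._accum(np.outer(a, g))
            elif a.ndim == 2 and b.ndim == 1:
                self._accum(np.outer(g, b))
                other._accum(a.T @ g)
            elif a.ndim == 1 and b.ndim == 1:
                self._accum(g * b)
                other._accum(g * a)
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
                self._accum(_unbroadcast(ga, a.shape))
                other._accum(_unbroadcast(gb, b.shape))

        out._backward = _bw
        return out

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0))
        out._prev = (self,)
        mask = self.data > 0

        def _bw(g):
            self._accum(g * mask)

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        s = _expit(self.data)
        out = Tensor(s)
        out._prev = (self,)

        def _bw(g):
            self._accum(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def log(self, eps: float = 1e-12) -> "Tensor":
        clipped = np.maximum(self.data, eps)
        out = Tensor(np.log(clipped))
        out._prev = (self,)

        def _bw(g):
            self._accum(g / clipped)

        out._backward = _bw
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))
        out._prev = (self,)
        shape = self.data.shape

        def _bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        """Max over one axis; gradient flows to the first argmax (ties)."""
        out_data = self.data.max(axis=axis)
        out = Tensor(out_data)
        out._prev = (self,)
        idx = np.argmax(self.data, axis=axis)

        def _bw(g):
            grad = np.zeros_like(self.data)
            np.put_along_axis(
                grad, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            self._accum(grad)

        out._backward = _bw
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape))
        out._prev = (self,)
        orig = self.data.shape

        def _bw(g):
            self._accum(g.reshape(orig))

        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes))
        out._prev = (self,)
        inv = np.argsort(axes)

        def _bw(g):
            self._accum(g.transpose(*inv))

        out._backward = _bw
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose(*range(self.ndim)[::-1])

    def take_last_axis(self, indices: np.ndarray) -> "Tensor":
        """Fancy-index the last axis with an integer array (im2col support)."""
        out = Tensor(self.data[..., indices])
        out._prev = (self,)
        shape = self.data.shape

        def _bw(g):
            grad = np.zeros(shape, dtype=float)
            flat = grad.reshape(-1, shape[-1])
            gflat = g.reshape(-1, *indices.shape)
            np.add.at(flat, (slice(None), indices), gflat)
            self._accum(grad)

        out._backward = _bw
        return out

    def unfold_last(self, k: int) -> "Tensor":
        """Sliding windows of width k over the last axis: (..., L) -> (..., L-k+1, k).

        The im2col step of 1-D convolution; backward is k shifted slice
        additions, far cheaper than a scatter-add.
        """
        length = self.data.shape[-1]
        l_out = length - k + 1
        if l_out < 1:
            raise ValueError(f"window {k} wider than axis length {length}")
        out = Tensor(np.stack([self.data[..., j : j + l_out] for j in range(k)], axis=-1))
        out._prev = (self,)
        shape = self.data.shape

        def _bw(g):
            grad = np.zeros(shape, dtype=float)
            for j in range(k):
                grad[..., j : j + l_out] += g[..., j]
            self._accum(grad)

        out._backward = _bw
        return out

    def slice_last(self, stop: int) -> "Tensor":
        """Keep the first `stop` entries of the last axis."""
        out = Tensor(self.data[..., :stop])
        out._prev = (self,)
        shape = self.data.shape

        def _bw(g):
            grad = np.zeros(shape, dtype=float)
            grad[..., :stop] = g
            self._accum(grad)

        out._backward = _bw
        return out

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Select rows (first axis) by integer index, with repeats allowed."""
        out = Tensor(self.data[indices])
        out._prev = (self,)
        shape = self.data.shape

        def _bw(g):
            grad = np.zeros(shape, dtype=float)
            np.add.at(grad, indices, g)
            self._accum(grad)

        out._backward = _bw
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool) -> "Tensor":
        """Inverted dropout; identity when not training or p == 0."""
        if not training or p <= 0.0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(mask)


def concat_rows(tensors: list) -> Tensor:
    """Concatenate 2-D tensors along axis 0."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=0))
    out._prev = tuple(tensors)
    sizes = [t.data.shape[0] for t in tensors]

    def _bw(g):
        ofs = 0
        for t, n in zip(tensors, sizes):
            t._accum(g[ofs : ofs + n])
            ofs += n

    out._backward = _bw
    return out


def binary_cross_entropy(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE of probabilities in (0,1) against 0/1 targets."""
    t = Tensor(np.asarray(targets, dtype=float))
    loss = -(t * probs.log() + (1.0 - t) * (1.0 - probs).log())
    return loss.mean()


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Weighted-mean softmax cross entropy; fused for stability.

    logits: (B, K); labels: (B,) ints; weights: per-sample, defaults to 1.
    """
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    sm = ez / ez.sum(axis=1, keepdims=True)
    b = z.shape[0]
    w = np.ones(b) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    nll = -np.log(np.maximum(sm[np.arange(b), labels], 1e-300))
    out = Tensor(float((w * nll).sum() / wsum))
    out._prev = (logits,)

    def _bw(g):
        grad = sm.copy()
        grad[np.arange(b), labels] -= 1.0
        grad *= (w / wsum)[:, None]
        logits._accum(g * grad)

    out._backward = _bw
    return out


def softmax_probs(logits: Tensor) -> np.ndarray:
    """Plain softmax on the forward values (no gradient), for scoring."""
    z = logits.data
    ez = np.exp(z - z.max(axis=-1, keepdims=True))
    return ez / ez.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with optional decoupled-style L2 (lambda * w added to the gradient)."""

    def __init__(self, params: list, lr: float = 1e-2, betas=(0.9, 0.999),
                 eps: float = 1e-8, l2: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.l2 * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    """Symmetric-uniform (Glorot) init for a (fan_out, fan_in) matrix."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))
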