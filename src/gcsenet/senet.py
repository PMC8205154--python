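"""Squeeze-and-excitation CNN classifier over the gene-axis channels.

Pipeline per candidate pair: 1-D convolution across the gene axis of the
(2 or 3)-channel feature tensor -> squeeze-and-excitation channel
reweighting -> max pooling -> fully connected hidden layer -> softmax
over {non-association, association}.

The SE block computes a per-channel global average ("squeeze"), passes
it through a bottleneck MLP with compression ratio r ("excitation",
s = sigmoid(W2 relu(W1 z))) and rescales each channel map by its gate
s_c in (0,1).  Gates forced to 1 reproduce the plain CNN exactly, which
is how the no-SE ablation is defined and tested.

Convolution kernel count/width, pool width and hidden size have no
standard reference values for this method; the defaults live in `RunConfig` and
are this package's own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import (
    Adam,
    Tensor,
    glorot,
    softmax_cross_entropy,
    softmax_probs,
)
from .config import RunConfig


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SE block primitives (array-level op surface)
# ---------------------------------------------------------------------------

@dataclass
class SEParams:
    """Bottleneck weights of the excitation MLP; hidden width = C // r."""

    w1: Tensor  # (C/r, C)
    w2: Tensor  # (C, C/r)
    r: int

    @staticmethod
    def init(c: int, r: int, rng: np.random.Generator) -> "SEParams":
        if r < 1 or c % r != 0:
            raise ModelError(f"channel count {c} must be divisible by SE ratio {r}")
        return SEParams(Tensor.param(glorot(rng, c // r, c)),
                        Tensor.param(glorot(rng, c, c // r)), r)


def se_squeeze(u: np.ndarray) -> np.ndarray:
    """Global average over the spatial axis: (.., C, L) -> (.., C)."""
    u = np.asarray(u, dtype=float)
    if u.ndim < 2 or u.shape[-1] < 1:
        raise ModelError(f"squeeze needs a (..., C, L>=1) map, got shape {u.shape}")
    return u.mean(axis=-1)


def se_excite(z: np.ndarray, p: SEParams) -> np.ndarray:
    """Gate vector sigmoid(W2 relu(W1 z)), entries strictly in (0, 1)."""
    z = np.asarray(z, dtype=float)
    hidden = np.maximum(z @ p.w1.data.T, 0.0)
    x = hidden @ p.w2.data.T
    return np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)), np.exp(x) / (1.0 + np.exp(x)))


def se_scale(u: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Channel-wise rescale: U'_c = s_c * U_c."""
    u, s = np.asarray(u, dtype=float), np.asarray(s, dtype=float)
    if u.shape[-2] != s.shape[-1]:
        raise ModelError(f"gate length {s.shape[-1]} != channel count {u.shape[-2]}")
    return u * s[..., :, None]


# ---------------------------------------------------------------------------
# Full classifier
# ---------------------------------------------------------------------------

@dataclass
class ClassifierParams:
    conv_w: Tensor          # (F, C_in * kernel)
    conv_b: Tensor          # (F,)
    se: SEParams | None
    fc1_w: Tensor           # (hidden, F * L_pool)
    fc1_b: Tensor
    fc2_w: Tensor           # (2, hidden)
    fc2_b: Tensor
    n_channels: int
    n_genes: int
    kernel: int
    pool: int

    def all_tensors(self) -> list[Tensor]:
        out = [self.conv_w, self.conv_b, self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b]
        if self.se is not None:
            out += [self.se.w1, self.se.w2]
        return out

    def n_params(self) -> int:
        return sum(t.data.size for t in self.all_tensors())


def init_classifier(n_channels: int, n_genes: int, config: RunConfig,
                    seed: int | None = None) -> ClassifierParams:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k, f, pool = config.kernel_width, config.conv_filters, config.pool_width
    l_out = n_genes - k + 1
    if l_out < 1:
        raise ModelError(f"kernel {k} wider than gene axis {n_genes}")
    l_pool = max(l_out // pool, 1)
    conv_w = Tensor.param(glorot(rng, f, n_channels * k))
    conv_b = Tensor.param(np.zeros(f))
    se = None if config.no_senet else SEParams.init(f, config.se_ratio, rng)
    fc1_w = Tensor.param(glorot(rng, config.fc_hidden, f * l_pool))
    fc1_b = Tensor.param(np.zeros(config.fc_hidden))
    fc2_w = Tensor.param(glorot(rng, 2, config.fc_hidden))
    fc2_b = Tensor.param(np.zeros(2))
    return ClassifierParams(conv_w, conv_b, se, fc1_w, fc1_b, fc2_w, fc2_b,
                            n_channels, n_genes, k, pool)


def forward_logits(params: ClassifierParams, x: Tensor, *, training: bool = False,
                   dropout: float = 0.0, rng: np.random.Generator | None = None,
                   force_unit_gate: bool = False) -> Tensor:
    """(B, C, n) feature tensor -> (B, 2) logits."""
    b, c, n = x.shape
    if c != params.n_channels or n != params.n_genes:
        raise ModelError(
            f"input shape {(c, n)} does not match model {(params.n_channels, params.n_genes)}"
        )
    k, pool = params.kernel, params.pool
    l_out = n - k + 1
    x = x.dropout(dropout, rng, training)
    # conv as im2col + matmul
    cols = x.unfold_last(k)                    # (B, C, L_out, k)
    cols = cols.transpose(0, 2, 1, 3).reshape(b, l_out, c * k)
    u = (cols @ params.conv_w.T + params.conv_b).relu()   # (B, L_out, F)
    u = u.transpose(0, 2, 1)                   # (B, F, L_out)
    if params.se is not None and not force_unit_gate:
        z = u.mean(axis=2)                     # squeeze: (B, F)
        s = ((z @ params.se.w1.T).relu() @ params.se.w2.T).sigmoid()
        f = u.shape[1]
        u = u * s.reshape(b, f, 1)             # excite + scale
    # max pooling (trim tail to a multiple of pool width)
    l_trim = (l_out // pool) * pool
    if l_trim < l_out:
        u = u.slice_last(l_trim)
    u = u.reshape(b, u.shape[1], l_trim // pool, pool).max(axis=3)
    flat = u.reshape(b, -1)
    flat = flat.dropout(dropout, rng, training)
    h = (flat @ params.fc1_w.T + params.fc1_b).relu()
    h = h.dropout(dropout, rng, training)
    return h @ params.fc2_w.T + params.fc2_b


def predict_proba(params: ClassifierParams, x: np.ndarray, **kw) -> np.ndarray:
    """Class-1 (association) probability per row, deterministic (no dropout)."""
    logits = forward_logits(params, Tensor(np.asarray(x, dtype=float)), **kw)
    return softmax_probs(logits)[:, 1]


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    config: RunConfig,
    seed: int | None = None,
) -> tuple[ClassifierParams, list[float]]:
    """Mini-batch Adam training of the classifier head.

    Class weighting: when one class outnumbers the other (the 10:1 ..
    100:1 negative-ratio settings), per-sample weights proportional to
    inverse class frequency keep the loss balanced; at 1:1 the weights
    are uniform.  Returns fitted params and the per-epoch mean train
    loss.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 3 or x.shape[0] != y.shape[0]:
        raise ModelError("features must be (n, channels, genes) aligned with labels")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError("training requires both positive and negative examples")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = init_classifier(x.shape[1], x.shape[2], config, seed=seed)
    opt = Adam(params.all_tensors(), lr=config.lr, l2=config.l2)
    n = x.shape[0]
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if max(n_pos, n_neg) > 1.5 * min(n_pos, n_neg):
        w_class = {0: n / (2.0 * n_neg), 1: n / (2.0 * n_pos)}
    else:
        w_class = {0: 1.0, 1: 1.0}
    weights = np.array([w_class[int(t)] for t in y])
    trace: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            if len(sel) < 2:
                continue
            opt.zero_grad()
            logits = forward_logits(
                params, Tensor(x[sel]), training=True,
                dropout=config.dropout, rng=rng,
            )
            loss = softmax_cross_entropy(logits, y[sel], weights[sel])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return params, trace
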