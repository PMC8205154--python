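"""Per-pair feature channels over the gene axis.

For a (disease d, miRNA m) candidate pair the classifier sees three
aligned channels of length n_genes:

    x_d[j]  = (1 + D_dg_j) * p(d, g_j)     disease-gene channel
    x_m[j]  = (1 + D_mg_j) * p(m, g_j)     miRNA-gene channel
    x_dm    = alpha * x_d + (1 - alpha) * x_m

where p(.,.) are the frozen bilinear decoder probabilities and D is the
reciprocal of the gene's typed degree (0 for isolated genes): a gene
linked to few diseases (or miRNAs) is up-weighted because its single
association says more about each partner.  Channels are z-scored with
statistics fitted on training pairs only and reused verbatim on test
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcn import GCNError, NodeEmbeddings, decode_all
from .hetnet import HetNet


class FeatureError(ValueError):
    pass


@dataclass(frozen=True)
class PairFeature:
    """Three gene-axis channels for one (disease, miRNA) candidate pair."""

    disease: str
    mirna: str
    gene_index: tuple[str, ...]
    x_d: np.ndarray
    x_m: np.ndarray
    x_dm: np.ndarray

    def stacked(self) -> np.ndarray:
        return np.stack([self.x_d, self.x_m, self.x_dm])


def degree_weight(net: HetNet, gene: str, side: str) -> float:
    """1 + 1/deg multiplier from the gene's disease- or miRNA-degree."""
    etype = {"disease": "dg", "mirna": "mg"}[side]
    deg = net.typed_degree(gene, etype)
    return 1.0 if deg == 0 else 1.0 + 1.0 / deg


def degree_multipliers(net: HetNet, side: str) -> np.ndarray:
    """degree_weight over the whole gene registry, in registry order."""
    return np.array([degree_weight(net, g, side) for g in net.genes])


def disease_gene_feature(
    d: str, emb: NodeEmbeddings, w_dg: np.ndarray, net: HetNet,
    gene_index: tuple[str, ...] | None = None,
) -> np.ndarray:
    """Weighted decoded disease-gene probabilities over the gene axis."""
    return _side_feature(d, emb, w_dg, net, "disease", gene_index)


def mirna_gene_feature(
    m: str, emb: NodeEmbeddings, w_mg: np.ndarray, net: HetNet,
    gene_index: tuple[str, ...] | None = None,
) -> np.ndarray:
    return _side_feature(m, emb, w_mg, net, "mirna", gene_index)


def _side_feature(node, emb, w_rel, net, side, gene_index):
    ids = emb.diseases if side == "disease" else emb.mirnas
    if node not in ids:
        raise GCNError(f"no embedding for {side} {node!r}")
    probs = decode_all(emb, w_rel, side)[ids.index(node)]
    mult = degree_multipliers(net, side)
    order = _gene_order(net, gene_index)
    return (mult * probs)[order]


def _gene_order(net: HetNet, gene_index) -> np.ndarray:
    if gene_index is None:
        return np.arange(len(net.genes))
    pos = {g: i for i, g in enumerate(net.genes)}
    try:
        return np.array([pos[g] for g in gene_index], dtype=int)
    except KeyError as e:
        raise FeatureError(f"gene {e.args[0]!r} not in network registry")


def combine(x_d: np.ndarray, x_m: np.ndarray, alpha: float) -> np.ndarray:
    """Convex mix of the two channels: alpha*x_d + (1-alpha)*x_m."""
    x_d, x_m = np.asarray(x_d, dtype=float), np.asarray(x_m, dtype=float)
    if x_d.shape != x_m.shape:
        raise FeatureError(f"channel length mismatch: {x_d.shape} vs {x_m.shape}")
    if not (0.0 < alpha < 1.0):
        raise FeatureError(f"alpha must be in (0,1), got {alpha}")
    return alpha * x_d + (1.0 - alpha) * x_m


class PairFeatureBuilder:
    """Precomputes both decode matrices once; assembles pairs by indexing.

    Ablations: `weighting=False` forces every degree multiplier to 1;
    `component=False` drops the combined channel (2-channel tensors);
    `use_gcn=False` replaces decoded probabilities with the raw 0/1
    adjacency of the network (the no-GCN variant).
    """

    def __init__(self, net: HetNet, emb: NodeEmbeddings | None, decoders: dict | None,
                 alpha: float = 0.57, *, weighting: bool = True, component: bool = True,
                 use_gcn: bool = True):
        self.net = net
        self.alpha = alpha
        self.weighting = weighting
        self.component = component
        self.gene_index = tuple(net.genes)
        self._didx = {d: i for i, d in enumerate(net.diseases)}
        self._midx = {m: i for i, m in enumerate(net.mirnas)}
        if use_gcn:
            if emb is None or decoders is None:
                raise FeatureError("embeddings and decoders required unless use_gcn=False")
            self.p_dg = decode_all(emb, _arr(decoders["dg"]), "disease")
            self.p_mg = decode_all(emb, _arr(decoders["mg"]), "mirna")
        else:
            self.p_dg = _adjacency(net, "dg")
            self.p_mg = _adjacency(net, "mg")
        mult_d = degree_multipliers(net, "disease")
        mult_m = degree_multipliers(net, "mirna")
        if not weighting:
            mult_d = np.ones_like(mult_d)
            mult_m = np.ones_like(mult_m)
        self.x_d_all = mult_d[None, :] * self.p_dg   # (n_d, n_g)
        self.x_m_all = mult_m[None, :] * self.p_mg   # (n_m, n_g)

    @property
    def n_channels(self) -> int:
        return 3 if self.component else 2

    def assemble_pair(self, d: str, m: str) -> PairFeature:
        x_d = self.x_d_all[self._didx[d]]
        x_m = self.x_m_all[self._midx[m]]
        x_dm = combine(x_d, x_m, self.alpha)
        return PairFeature(d, m, self.gene_index, x_d, x_m, x_dm)

    def tensor(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        """Stacked (n_pairs, channels, n_genes) feature tensor."""
        try:
            di = np.array([self._didx[d] for _m, d in pairs], dtype=int)
            mi = np.array([self._midx[m] for m, _d in pairs], dtype=int)
        except KeyError as e:
            raise FeatureError(f"unknown pair member {e.args[0]!r}")
        x_d = self.x_d_all[di]
        x_m = self.x_m_all[mi]
        chans = [x_d, x_m]
        if self.component:
            chans.append(combine(x_d, x_m, self.alpha))
        return np.stack(chans, axis=1)


def _arr(w):
    return w.data if hasattr(w, "data") else np.asarray(w)


def _adjacency(net: HetNet, etype: str) -> np.ndarray:
    rows = {"dg": net.diseases, "mg": net.mirnas}[etype]
    ri = {x: i for i, x in enumerate(rows)}
    gi = {g: i for i, g in enumerate(net.genes)}
    a = np.zeros((len(rows), len(net.genes)))
    for u, v, _w in net.edges.get(etype, ()):
        a[ri[u], gi[v]] = 1.0
    return a


class ChannelNormalizer:
    """Per-channel, per-gene z-scoring with train-set statistics only.

    `fit` must be called on the training tensor before any `transform`;
    positions with zero spread pass through unscaled.  The fit counter
    exists so leakage tests can assert statistics are never refitted.
    """

    def __init__(self):
        self.mean = None
        self.sd = None
        self.fit_count = 0

    def fit(self, x: np.ndarray) -> "ChannelNormalizer":
        x = np.asarray(x, dtype=float)
        if x.ndim != 3:
            raise FeatureError("expected (pairs, channels, genes) tensor")
        self.mean = x.mean(axis=0)
        self.sd = x.std(axis=0)
        self.fit_count += 1
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise FeatureError("normalizer used before fit()")
        x = np.asarray(x, dtype=float)
        sd = np.where(self.sd > 0, self.sd, 1.0)
        return (x - self.mean) / sd

    def fit_transform(self, x: np.ndarray) -> np.ndarray:
        return self.fit(x).transform(x)
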