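"""Three-layer disease-gene-miRNA heterogeneous network assembly.

The network has three typed node registries and five weighted edge sets:
within-type similarity edges (disease-disease, miRNA-miRNA, gene-gene)
and bipartite association edges (disease-gene, miRNA-gene).  Similarity
matrices are sparsified to k-nearest-neighbour edge lists so the graph
stays tractable; the similarity value itself becomes the edge weight and
is used multiplicatively during message passing.

miRNA-disease labels are NOT part of the network: they live in a separate
`AssociationMatrix` so that held-out evaluation pairs can never leak into
the encoder through graph structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ontology import SimilarityMatrix

EDGE_TYPES = ("dd", "mm", "gg", "dg", "mg")
_WITHIN = {"dd": "disease", "mm": "mirna", "gg": "gene"}
_BIPART = {"dg": ("disease", "gene"), "mg": ("mirna", "gene")}


class NetworkError(ValueError):
    """Identifier, typing or structural errors while assembling the network."""


@dataclass(frozen=True)
class HetNet:
    """Typed node registries plus five canonical weighted edge sets."""

    diseases: tuple[str, ...]
    genes: tuple[str, ...]
    mirnas: tuple[str, ...]
    edges: dict[str, frozenset[tuple[str, str, float]]]

    def __post_init__(self):
        reg = {"disease": set(self.diseases), "gene": set(self.genes), "mirna": set(self.mirnas)}
        seen: dict[str, str] = {}
        for tname, ids in reg.items():
            for i in ids:
                if i in seen:
                    raise NetworkError(f"id {i!r} registered under both {seen[i]} and {tname}")
                seen[i] = tname
        for etype in EDGE_TYPES:
            for a, b, w in self.edges.get(etype, ()):
                if not (0.0 <= w <= 1.0):
                    raise NetworkError(f"{etype} edge ({a},{b}) weight {w} outside [0,1]")
                if etype in _WITHIN:
                    t = _WITHIN[etype]
                    if a not in reg[t] or b not in reg[t]:
                        raise NetworkError(f"{etype} edge endpoint not a {t}: ({a},{b})")
                    if not a < b:
                        raise NetworkError(f"{etype} edge ({a},{b}) not canonically ordered")
                else:
                    ta, tb = _BIPART[etype]
                    if a not in reg[ta] or b not in reg[tb]:
                        raise NetworkError(
                            f"{etype} edge ({a},{b}) endpoints must be ({ta},{tb})"
                        )
                    if a == b:
                        raise NetworkError(f"self-loop in bipartite edge set {etype}: {a!r}")

    def node_type(self, node: str) -> str:
        for t, ids in (("disease", self.diseases), ("gene", self.genes), ("mirna", self.mirnas)):
            if node in ids:
                return t
        raise NetworkError(f"unknown node: {node!r}")

    def typed_degree(self, node: str, edge_type: str) -> int:
        """Number of edges of `edge_type` incident to `node`."""
        if edge_type not in EDGE_TYPES:
            raise NetworkError(f"unknown edge type: {edge_type!r}")
        self.node_type(node)  # raises on unknown node
        return sum(1 for a, b, _ in self.edges.get(edge_type, ()) if node in (a, b))

    def validate(self) -> None:
        """Re-run construction invariants (no-op if the instance is intact)."""
        self.__post_init__()


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary miRNA x disease label matrix; 1 = known association, 0 = unobserved."""

    mirna_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray
    _mi: dict = field(init=False, repr=False, compare=False)
    _di: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.shape != (len(self.mirna_ids), len(self.disease_ids)):
            raise NetworkError("association matrix shape mismatch")
        if not np.isin(v, (0, 1)).all():
            raise NetworkError("association matrix entries must be 0 or 1")
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "_mi", {m: i for i, m in enumerate(self.mirna_ids)})
        object.__setattr__(self, "_di", {d: i for i, d in enumerate(self.disease_ids)})

    @staticmethod
    def from_pairs(pairs, mirna_ids=None, disease_ids=None) -> "AssociationMatrix":
        """Build from (mirna, disease, label) triples; missing cells are 0."""
        pairs = [(str(m), str(d), int(v)) for m, d, v in pairs]
        mids = tuple(sorted({m for m, _, _ in pairs})) if mirna_ids is None else tuple(mirna_ids)
        dids = tuple(sorted({d for _, d, _ in pairs})) if disease_ids is None else tuple(disease_ids)
        mi = {m: i for i, m in enumerate(mids)}
        di = {d: i for i, d in enumerate(dids)}
        vals = np.zeros((len(mids), len(dids)), dtype=np.int8)
        for m, d, v in pairs:
            if v not in (0, 1):
                raise NetworkError(f"label for ({m},{d}) must be 0 or 1, got {v}")
            vals[mi[m], di[d]] = v
        return AssociationMatrix(mids, dids, vals)

    def positives(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.values)
        return [(self.mirna_ids[r], self.disease_ids[c]) for r, c in zip(rows, cols)]


def sparsify_similarity(sim: SimilarityMatrix, k: int) -> list[tuple[str, str, float]]:
    """k-nearest-neighbour edges from a similarity matrix.

    Each node links to its k most similar distinct neighbours (ties broken
    by identifier order); the union over both directions is returned as a
    canonically ordered edge list, so degrees may exceed k.
    """
    if k < 1:
        raise NetworkError(f"k must be >= 1, got {k}")
    n = len(sim.ids)
    if n < 2:
        return []
    if k >= n:
        warnings.warn(f"k={k} >= {n} nodes; capped at {n - 1}", stacklevel=2)
        k = n - 1
    edges: set[tuple[str, str, float]] = set()
    for i, a in enumerate(sim.ids):
        # sort neighbours by (-similarity, id): value desc, id asc on ties
        order = sorted(
            (j for j in range(n) if j != i),
            key=lambda j: (-sim.values[i, j], sim.ids[j]),
        )
        for j in order[:k]:
            b = sim.ids[j]
            lo, hi = (a, b) if a < b else (b, a)
            edges.add((lo, hi, float(sim.values[i, j])))
    return sorted(edges)


def build_hetnet(
    dd_sim: SimilarityMatrix,
    mm_sim: SimilarityMatrix,
    gg_edges,
    dg_edges,
    mg_edges,
    k: int = 15,
) -> HetNet:
    """Assemble the heterogeneous network from similarities and edge lists.

    dd/mm edges come from k-NN sparsification of the similarity matrices;
    gg/dg/mg from explicit (a, b[, weight]) rows with weight defaulting to
    1.0.  Registries are the sorted union of ids seen per type.  Diseases
    with no disease-gene edge are dropped (the encoder can say nothing
    about them through the gene layer).
    """
    dg = _norm_rows(dg_edges, "dg")
    mg = _norm_rows(mg_edges, "mg")
    gg = _norm_rows(gg_edges, "gg")

    linked_d = {a for a, _, _ in dg}
    diseases = tuple(sorted(set(dd_sim.ids) | linked_d))
    dropped = [d for d in diseases if d not in linked_d]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} disease(s) with no gene association", stacklevel=2
        )
        diseases = tuple(d for d in diseases if d in linked_d)
    mirnas = tuple(sorted(set(mm_sim.ids) | {a for a, _, _ in mg}))
    genes = tuple(sorted({b for _, b, _ in dg} | {b for _, b, _ in mg}
                         | {x for a, b, _ in gg for x in (a, b)}))

    dd = [e for e in sparsify_similarity(dd_sim, k) if e[0] in set(diseases) and e[1] in set(diseases)]
    mm = sparsify_similarity(mm_sim, k)
    gg_canon = set()
    for a, b, w in gg:
        if a == b:
            continue
        lo, hi = (a, b) if a < b else (b, a)
        gg_canon.add((lo, hi, w))
    edges = {
        "dd": frozenset(dd),
        "mm": frozenset(mm),
        "gg": frozenset(gg_canon),
        "dg": frozenset(dg),
        "mg": frozenset(mg),
    }
    return HetNet(diseases, genes, mirnas, edges)


def _norm_rows(rows, etype: str) -> list[tuple[str, str, float]]:
    out = []
    for lineno, row in enumerate(rows, start=1):
        if len(row) == 2:
            a, b, w = row[0], row[1], 1.0
        elif len(row) == 3:
            a, b, w = row
        else:
            raise NetworkError(f"{etype} row {lineno}: expected 2 or 3 fields, got {len(row)}")
        try:
            w = float(w)
        except (TypeError, ValueError):
            raise NetworkError(f"{etype} row {lineno}: non-numeric weight {w!r}")
        out.append((str(a), str(b), w))
    return out


def typed_degree(net: HetNet, node: str, edge_type: str) -> int:
    return net.typed_degree(node, edge_type)


def hetnet_from_edge_lists(dd, mm, gg, dg, mg, drop_unlinked_diseases: bool = True) -> HetNet:
    """Assemble a HetNet from five pre-sparsified weighted edge lists.

    Counterpart of `build_hetnet` for re-loading networks that were
    already written to disk (dd/mm edges given explicitly instead of as
    similarity matrices).  Within-type edges are canonicalised; the
    no-gene-association disease filter is applied as at build time.
    """
    lists = {"dd": _norm_rows(dd, "dd"), "mm": _norm_rows(mm, "mm"),
             "gg": _norm_rows(gg, "gg"), "dg": _norm_rows(dg, "dg"),
             "mg": _norm_rows(mg, "mg")}
    canon = {}
    for etype in ("dd", "mm", "gg"):
        s = set()
        for a, b, w in lists[etype]:
            if a == b:
                continue
            lo, hi = (a, b) if a < b else (b, a)
            s.add((lo, hi, w))
        canon[etype] = s
    linked_d = {a for a, _, _ in lists["dg"]}
    diseases = {x for a, b, _ in canon["dd"] for x in (a, b)} | linked_d
    if drop_unlinked_diseases:
        dropped = diseases - linked_d
        if dropped:
            warnings.warn(
                f"dropping {len(dropped)} disease(s) with no gene association",
                stacklevel=2,
            )
        diseases = linked_d
        canon["dd"] = {e for e in canon["dd"] if e[0] in diseases and e[1] in diseases}
    mirnas = {x for a, b, _ in canon["mm"] for x in (a, b)} | {a for a, _, _ in lists["mg"]}
    genes = ({x for a, b, _ in canon["gg"] for x in (a, b)}
             | {b for _, b, _ in lists["dg"]} | {b for _, b, _ in lists["mg"]})
    edges = {
        "dd": frozenset(canon["dd"]),
        "mm": frozenset(canon["mm"]),
        "gg": frozenset(canon["gg"]),
        "dg": frozenset(lists["dg"]),
        "mg": frozenset(lists["mg"]),
    }
    return HetNet(tuple(sorted(diseases)), tuple(sorted(genes)), tuple(sorted(mirnas)), edges)
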