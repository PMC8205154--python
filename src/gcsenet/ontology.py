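"""Ontology-based similarity measures over disease / phenotype term DAGs.

Three measures used to build the similarity layers of the heterogeneous
network:

* DAG-decay **disease semantic similarity**: each disease term D induces a
  semantic profile over its ancestor closure T(D), where an ancestor d
  contributes D_d(d) = max over children of Δ·(child's contribution), with
  D_d(D) = 1.  Two diseases are similar in proportion to the contributions
  of their shared ancestors, normalised by their total semantic values.
* **miRNA functional similarity** (best-match average): two miRNAs are
  similar when the disease sets they are associated with are similar,
  scored by averaging each disease's best match in the other set.
* **Resnik phenotype similarity**: -log of the annotation frequency of the
  most informative (fewest-annotated) common ancestor, with gene
  annotations propagated up the DAG.

Terms are opaque, case-sensitive string identifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


class OntologyError(ValueError):
    """Structural or identifier errors in ontology inputs."""


@dataclass(frozen=True)
class TermDAG:
    """Rooted multi-parent acyclic hierarchy of terms.

    Edges are (child, parent) pairs: parents are more general terms.
    """

    terms: frozenset[str]
    edges: frozenset[tuple[str, str]]
    _parents: dict = field(init=False, repr=False, compare=False)
    _children: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        for c, p in self.edges:
            if c not in self.terms or p not in self.terms:
                raise OntologyError(f"edge endpoint not a registered term: ({c}, {p})")
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)  # child -> parent
        if not nx.is_directed_acyclic_graph(g):
            raise OntologyError("term hierarchy contains a directed cycle")
        parents: dict[str, set[str]] = {t: set() for t in self.terms}
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for c, p in self.edges:
            parents[c].add(p)
            children[p].add(c)
        if not any(not ps for ps in parents.values()):
            raise OntologyError("hierarchy has no root (every term has a parent)")
        object.__setattr__(self, "_parents", parents)
        object.__setattr__(self, "_children", children)

    @staticmethod
    def from_edges(edges) -> "TermDAG":
        edges = [(str(c), str(p)) for c, p in edges]
        terms = {t for e in edges for t in e}
        return TermDAG(frozenset(terms), frozenset(edges))

    def parents(self, term: str) -> set[str]:
        return set(self._parents[term])

    def children(self, term: str) -> set[str]:
        return set(self._children[term])

    def roots(self) -> set[str]:
        return {t for t, ps in self._parents.items() if not ps}

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        """Reflexive-transitive parent closure of `term`."""
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term!r}")
        seen: set[str] = set()
        stack = list(self._parents[term])
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self._parents[t])
        if include_self:
            seen.add(term)
        return seen

    def descendants(self, term: str, include_self: bool = True) -> set[str]:
        if term not in self.terms:
            raise OntologyError(f"unknown term: {term!r}")
        seen: set[str] = set()
        stack = list(self._children[term])
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            stack.extend(self._children[t])
        if include_self:
            seen.add(term)
        return seen


@dataclass(frozen=True)
class SemanticProfile:
    """Decayed ancestor contributions D_d(·) of one target term, plus their sum DV."""

    target: str
    contributions: dict[str, float]
    dv: float
    delta: float


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity over an ordered id list, values in [0, 1]."""

    ids: tuple[str, ...]
    values: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise OntologyError("similarity matrix shape does not match id list")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {t: i for i, t in enumerate(self.ids)})
        if len(self._index) != len(self.ids):
            raise OntologyError("duplicate identifiers in similarity matrix")

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as e:
            raise OntologyError(f"identifier not in similarity matrix: {e.args[0]!r}")

    def __contains__(self, a: str) -> bool:
        return a in self._index


@dataclass(frozen=True)
class AnnotationMap:
    """Direct and descendant-propagated term -> gene annotation sets."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    total_genes: int


# ---------------------------------------------------------------------------
# Disease semantic similarity
# ---------------------------------------------------------------------------

def semantic_contributions(dag: TermDAG, target: str, delta: float = 0.5) -> SemanticProfile:
    """Decayed semantic contribution of every ancestor of `target`.

    The target contributes 1; any other ancestor d contributes
    Δ · max over its children within the ancestor closure.  Equivalently,
    Δ ** (shortest directed path length from d down to target).
    """
    if target not in dag.terms:
        raise OntologyError(f"unknown target term: {target!r}")
    if not (0.0 < delta < 1.0):
        raise OntologyError(f"decay factor must be in (0, 1), got {delta}")
    closure = dag.ancestors(target)
    contrib: dict[str, float] = {target: 1.0}
    # process ancestors bottom-up: a term's value needs its children's values
    order = [t for t in _topo_child_first(dag, closure) if t != target]
    for t in order:
        kids = [c for c in dag.children(t) if c in closure]
        contrib[t] = delta * max(contrib[c] for c in kids)
    return SemanticProfile(target, contrib, float(sum(contrib.values())), delta)


def _topo_child_first(dag: TermDAG, closure: set[str]) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(closure)
    for c, p in dag.edges:
        if c in closure and p in closure:
            g.add_edge(c, p)
    return list(nx.topological_sort(g))


def disease_semantic_similarity(profile_i: SemanticProfile, profile_j: SemanticProfile) -> float:
    """Shared-ancestor contribution ratio between two semantic profiles."""
    if profile_i.delta != profile_j.delta:
        raise OntologyError(
            f"profiles built with different decay factors: "
            f"{profile_i.delta} vs {profile_j.delta}"
        )
    shared = profile_i.contributions.keys() & profile_j.contributions.keys()
    if not shared:
        return 0.0
    num = sum(profile_i.contributions[t] + profile_j.contributions[t] for t in shared)
    return num / (profile_i.dv + profile_j.dv)


def pairwise_disease_similarity(
    dag: TermDAG, terms: list[str], delta: float = 0.5
) -> SimilarityMatrix:
    """Symmetric unit-diagonal similarity matrix over the given disease terms."""
    if len(set(terms)) != len(terms):
        raise OntologyError("duplicate term ids in similarity request")
    profiles = [semantic_contributions(dag, t, delta) for t in terms]
    n = len(terms)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = disease_semantic_similarity(profiles[i], profiles[j])
    return SimilarityMatrix(tuple(terms), vals)


# ---------------------------------------------------------------------------
# miRNA functional similarity (best-match average over disease sets)
# ---------------------------------------------------------------------------

def best_match_similarity(dt: str, DT: set[str], sim: SimilarityMatrix) -> float:
    if not DT:
        raise OntologyError("best-match similarity against an empty disease set is undefined")
    return max(sim.loc(dt, d) for d in DT)


def mirna_functional_similarity(set1: set[str], set2: set[str], sim: SimilarityMatrix) -> float:
    """Best-match-average similarity between two miRNAs' disease sets."""
    if not set1 or not set2:
        raise OntologyError(
            "miRNA functional similarity is undefined for a miRNA with no "
            "associated diseases; filter disease-less miRNAs upstream"
        )
    total = sum(best_match_similarity(d, set2, sim) for d in set1)
    total += sum(best_match_similarity(d, set1, sim) for d in set2)
    return total / (len(set1) + len(set2))


def pairwise_mirna_similarity(
    disease_sets: dict[str, set[str]], sim: SimilarityMatrix
) -> SimilarityMatrix:
    """Functional similarity matrix over miRNAs from their disease sets."""
    ids = tuple(disease_sets)
    n = len(ids)
    vals = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = mirna_functional_similarity(
                disease_sets[ids[i]], disease_sets[ids[j]], sim
            )
    return SimilarityMatrix(ids, vals)


# ---------------------------------------------------------------------------
# Resnik phenotype similarity
# ---------------------------------------------------------------------------

def propagate_annotations(dag: TermDAG, direct: dict[str, set[str]]) -> AnnotationMap:
    """Propagate gene annotations from descendants up to every term."""
    for t in direct:
        if t not in dag.terms:
            raise OntologyError(f"annotation refers to unknown term: {t!r}")
    all_genes: set[str] = set()
    direct_full = {t: frozenset(direct.get(t, ())) for t in dag.terms}
    propagated: dict[str, frozenset[str]] = {}
    # reverse topological order over child->parent edges puts children first
    g = nx.DiGraph()
    g.add_nodes_from(dag.terms)
    g.add_edges_from(dag.edges)
    for t in nx.topological_sort(g):
        acc = set(direct_full[t])
        for c in dag.children(t):
            acc |= propagated[c]
        propagated[t] = frozenset(acc)
        all_genes |= direct_full[t]
    return AnnotationMap(direct_full, propagated, len(all_genes))


def resnik_similarity(dag: TermDAG, ann: AnnotationMap, p1: str, p2: str) -> float:
    """-ln(N_pm / N) for the common ancestor pm with fewest (>0) annotations.

    The common-ancestor set is reflexive: each term counts among its own
    ancestors, so a term subsuming the other can itself be the minimum.
    Natural logarithm; the base only rescales all similarities.
    """
    common = dag.ancestors(p1) & dag.ancestors(p2)
    counts = [len(ann.propagated[t]) for t in common if len(ann.propagated[t]) > 0]
    if not counts:
        raise OntologyError(
            f"no common ancestor of {p1!r} and {p2!r} carries gene annotations"
        )
    n_pm = min(counts)
    if ann.total_genes <= 0:
        raise OntologyError("annotation map covers zero genes")
    return -math.log(n_pm / ann.total_genes)
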