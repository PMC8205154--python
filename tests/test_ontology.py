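"""Ontology similarity measures against brute-force oracles and closed forms."""

import math

import numpy as np
import pytest

from gcsenet.ontology import (
    OntologyError,
    SimilarityMatrix,
    TermDAG,
    best_match_similarity,
    disease_semantic_similarity,
    mirna_functional_similarity,
    pairwise_disease_similarity,
    pairwise_mirna_similarity,
    propagate_annotations,
    resnik_similarity,
    semantic_contributions,
)
from gcsenet.synthetic import generate_dag

from oracles import closure_oracle, contributions_oracle, similarity_oracle


# ---------------------------------------------------------------------------
# Semantic contributions
# ---------------------------------------------------------------------------

def test_chain_contributions_and_dv():
    dag = TermDAG.from_edges([("A", "root"), ("B", "A")])
    prof = semantic_contributions(dag, "B", 0.5)
    assert prof.contributions == {"B": 1.0, "A": 0.5, "root": 0.25}
    assert prof.dv == pytest.approx(1.75)


def test_shortcut_edge_dominates_via_max_rule():
    # root is 2 steps above C through A/B, but a direct edge makes it 1 step
    dag = TermDAG.from_edges([("A", "root"), ("B", "root"), ("C", "A"), ("C", "B")])
    assert semantic_contributions(dag, "C", 0.5).contributions["root"] == pytest.approx(0.25)
    dag2 = TermDAG.from_edges(
        [("A", "root"), ("B", "root"), ("C", "A"), ("C", "B"), ("C", "root")]
    )
    assert semantic_contributions(dag2, "C", 0.5).contributions["root"] == pytest.approx(0.5)


def test_contributions_match_path_enumeration_oracle_on_random_dags():
    failures = 0
    for seed in range(50):
        dag = generate_dag(n_terms=int(5 + seed % 26), branching=3,
                           extra_edges=seed % 7, seed=seed)
        terms = sorted(dag.terms)
        rng = np.random.default_rng(seed)
        for target in rng.choice(terms, size=min(5, len(terms)), replace=False):
            prof = semantic_contributions(dag, str(target), 0.5)
            oracle = contributions_oracle(dag, str(target), 0.5)
            assert prof.contributions.keys() == oracle.keys()
            for t, v in oracle.items():
                if abs(prof.contributions[t] - v) > 1e-12:
                    failures += 1
    assert failures == 0


def test_unknown_target_and_cycle_rejected():
    dag = TermDAG.from_edges([("A", "root")])
    with pytest.raises(OntologyError):
        semantic_contributions(dag, "nope", 0.5)
    with pytest.raises(OntologyError):
        TermDAG.from_edges([("A", "B"), ("B", "A")])


# ---------------------------------------------------------------------------
# Disease semantic similarity
# ---------------------------------------------------------------------------

def test_sibling_similarity_closed_form():
    dag = TermDAG.from_edges([("A", "R"), ("B", "R")])
    pa = semantic_contributions(dag, "A", 0.5)
    pb = semantic_contributions(dag, "B", 0.5)
    assert disease_semantic_similarity(pa, pb) == pytest.approx(1.0 / 3.0)
    assert disease_semantic_similarity(pa, pa) == pytest.approx(1.0)


def test_disconnected_components_have_zero_similarity():
    dag = TermDAG.from_edges([("A", "R1"), ("B", "R2")])
    pa = semantic_contributions(dag, "A", 0.5)
    pb = semantic_contributions(dag, "B", 0.5)
    assert disease_semantic_similarity(pa, pb) == 0.0


def test_mismatched_delta_rejected():
    dag = TermDAG.from_edges([("A", "R"), ("B", "R")])
    pa = semantic_contributions(dag, "A", 0.5)
    pb = semantic_contributions(dag, "B", 0.4)
    with pytest.raises(OntologyError):
        disease_semantic_similarity(pa, pb)


def test_pairwise_similarity_matches_oracle_and_is_well_formed():
    for seed in range(50):
        dag = generate_dag(n_terms=int(6 + seed % 25), branching=3,
                           extra_edges=seed % 5, seed=1000 + seed)
        terms = sorted(dag.terms)[:8]
        sim = pairwise_disease_similarity(dag, terms, 0.5)
        v = sim.values
        np.testing.assert_allclose(v, v.T, atol=0)
        np.testing.assert_allclose(np.diag(v), 1.0, atol=0)
        assert ((v >= 0) & (v <= 1 + 1e-15)).all()
        for i, a in enumerate(terms):
            for j, b in enumerate(terms):
                assert abs(v[i, j] - similarity_oracle(dag, a, b, 0.5)) < 1e-12


def test_pairwise_similarity_permutation_equivariant():
    dag = generate_dag(12, extra_edges=3, seed=5)
    terms = sorted(dag.terms)[:6]
    sim1 = pairwise_disease_similarity(dag, terms, 0.5)
    perm = terms[::-1]
    sim2 = pairwise_disease_similarity(dag, perm, 0.5)
    for i, a in enumerate(terms):
        for j, b in enumerate(terms):
            assert sim1.values[i, j] == pytest.approx(sim2.loc(a, b), abs=0)
    with pytest.raises(OntologyError):
        pairwise_disease_similarity(dag, [terms[0], terms[0]], 0.5)


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------

@pytest.fixture()
def sim3():
    return SimilarityMatrix(("A", "B", "C"),
                            np.array([[1.0, 1 / 3, 0.2],
                                      [1 / 3, 1.0, 0.7],
                                      [0.2, 0.7, 1.0]]))


def test_best_match_is_max_over_set(sim3):
    assert best_match_similarity("A", {"A", "B"}, sim3) == 1.0
    assert best_match_similarity("A", {"C"}, sim3) == pytest.approx(0.2)
    assert best_match_similarity("A", {"B", "C"}, sim3) == pytest.approx(1 / 3)
    with pytest.raises(OntologyError):
        best_match_similarity("A", set(), sim3)


def test_mirna_similarity_closed_forms(sim3):
    assert mirna_functional_similarity({"A"}, {"B"}, sim3) == pytest.approx(1 / 3)
    assert mirna_functional_similarity({"A", "B"}, {"A", "B"}, sim3) == 1.0
    zero = SimilarityMatrix(("A", "B"), np.eye(2))
    assert mirna_functional_similarity({"A"}, {"B"}, zero) == 0.0
    with pytest.raises(OntologyError):
        mirna_functional_similarity(set(), {"A"}, sim3)


def test_mirna_similarity_symmetric(sim3):
    s1 = mirna_functional_similarity({"A", "C"}, {"B"}, sim3)
    s2 = mirna_functional_similarity({"B"}, {"A", "C"}, sim3)
    assert s1 == pytest.approx(s2, abs=0)
    m = pairwise_mirna_similarity({"m1": {"A", "C"}, "m2": {"B"}}, sim3)
    assert m.loc("m1", "m2") == pytest.approx(s1)
    assert m.loc("m1", "m1") == 1.0


# ---------------------------------------------------------------------------
# Annotation propagation + Resnik
# ---------------------------------------------------------------------------

def test_propagation_chain_example():
    dag = TermDAG.from_edges([("A", "R"), ("B", "A")])
    ann = propagate_annotations(dag, {"B": {"g1"}, "A": {"g2"}, "R": set()})
    assert ann.propagated["R"] == {"g1", "g2"}
    assert ann.propagated["A"] == {"g1", "g2"}
    assert ann.propagated["B"] == {"g1"}
    assert ann.total_genes == 2


def test_propagation_matches_closure_oracle_on_random_dags():
    for seed in range(20):
        dag = generate_dag(15, extra_edges=4, seed=seed)
        rng = np.random.default_rng(seed)
        direct = {t: {f"g{rng.integers(10)}" for _ in range(rng.integers(3))}
                  for t in dag.terms}
        ann = propagate_annotations(dag, direct)
        for t in dag.terms:
            assert ann.propagated[t] == closure_oracle(dag, direct, t)
            assert ann.direct[t] <= ann.propagated[t]
        for c, p in dag.edges:
            assert ann.propagated[p] >= ann.propagated[c]


def test_resnik_closed_forms():
    dag = TermDAG.from_edges([("A", "R"), ("B", "R")])
    genes = [f"g{i}" for i in range(10)]
    ann = propagate_annotations(dag, {"R": set(), "A": set(genes[:5]), "B": set(genes[5:])})
    # common ancestor of A and B is R with all 10 genes -> -ln(1) = 0
    assert resnik_similarity(dag, ann, "A", "B") == pytest.approx(0.0)
    # self-similarity of A: S includes A itself with 5 genes -> -ln(0.5)
    assert resnik_similarity(dag, ann, "A", "A") == pytest.approx(-math.log(0.5), abs=1e-9)


def test_resnik_monotone_in_ancestor_count():
    dag = TermDAG.from_edges([("A", "R"), ("B", "R")])
    base = {"R": set(), "A": {"g1"}, "B": {"g2", "g3"}}
    ann1 = propagate_annotations(dag, base)
    s1 = resnik_similarity(dag, ann1, "A", "B")
    # add a gene to the minimal common ancestor's closure -> similarity drops
    ann2 = propagate_annotations(dag, {**base, "R": {"g4"}})
    s2 = resnik_similarity(dag, ann2, "A", "B")
    assert s2 <= s1
    with pytest.raises(OntologyError):
        dag2 = TermDAG.from_edges([("A", "R1"), ("B", "R2")])
        resnik_similarity(dag2, propagate_annotations(dag2, {"A": {"g"}}), "A", "B")
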