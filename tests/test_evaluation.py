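"""Negative sampling, fold construction and metric oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gcsenet as g
from oracles import aupr_oracle, auroc_oracle, confusion_oracle
from gcsenet.evaluation import (
    EvaluationError,
    fold_metrics,
    gene_overlap_baseline,
    recompute_report,
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def test_perfect_and_random_ranking_limits():
    y = [0] * 50 + [1] * 50
    s = np.linspace(0, 1, 100)
    assert g.auroc(y, s) == 1.0
    assert g.aupr(y, s) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    y2 = rng.integers(0, 2, size=4000)
    s2 = rng.random(4000)
    assert abs(g.auroc(y2, s2) - 0.5) < 0.03


@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_exhaustive_oracles_with_ties(seed):
    rng = np.random.default_rng(seed)
    n = 200 if seed else 500
    y = rng.integers(0, 2, size=n)
    y[:2] = [0, 1]
    s = np.round(rng.random(n), 2)  # heavy ties
    assert abs(g.auroc(y, s) - auroc_oracle(y, s)) < 1e-12
    assert abs(g.aupr(y, s) - aupr_oracle(y, s)) < 1e-12
    m = g.confusion_metrics(y, s)
    p, r, f1 = confusion_oracle(y, s)
    assert m["precision"] == pytest.approx(p, abs=1e-12)
    assert m["recall"] == pytest.approx(r, abs=1e-12)
    assert m["f1"] == pytest.approx(f1, abs=1e-12)


def test_confusion_example_and_undefined_cases():
    # TP=8, FP=2, FN=2
    y = [1] * 8 + [0] * 2 + [1] * 2 + [0] * 8
    s = [0.9] * 10 + [0.1] * 10
    m = g.confusion_metrics(y, s)
    assert (m["precision"], m["recall"], m["f1"]) == (0.8, 0.8, pytest.approx(0.8))
    with pytest.warns(UserWarning, match="precision undefined"):
        m2 = g.confusion_metrics([1, 0], [0.1, 0.2])
    assert np.isnan(m2["precision"])
    with pytest.raises(EvaluationError):
        g.auroc([1, 1], [0.2, 0.3])
    with pytest.raises(EvaluationError):
        g.aupr([0, 0], [0.2, 0.3])


# ---------------------------------------------------------------------------
# Sampling and folds
# ---------------------------------------------------------------------------

def test_negative_sampling_sizes_and_disjointness(tiny_ds):
    y = tiny_ds.labels
    pos = set(y.positives())
    for ratio in (1.0, 3.0):
        neg = g.sample_negatives(y, ratio, seed=5)
        assert len(neg) == round(ratio * len(pos))
        assert len(set(neg)) == len(neg)
        assert not (set(neg) & pos)
    n1 = g.sample_negatives(y, 1.0, seed=5)
    assert n1 == g.sample_negatives(y, 1.0, seed=5)
    with pytest.raises(EvaluationError, match="maximum feasible ratio"):
        g.sample_negatives(y, 1e6, seed=0)


@given(n=st.integers(20, 120), k=st.integers(2, 8), seed=st.integers(0, 1000))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_folds_always_partition_the_pairs(n, k, seed):
    """Every labeled pair lands in exactly one fold under both modes."""
    pairs = [(f"m{i}", f"d{i % 15}") for i in range(n)]
    for grouping in ("by-pair", "by-disease"):
        if grouping == "by-disease" and min(n, 15) < k:
            continue
        plan = g.make_folds(pairs, k=k, grouping=grouping, seed=seed)
        assert sorted(p for i in range(k) for p in plan.fold(i)) == sorted(pairs)
        if grouping == "by-disease":
            for i in range(k):
                diseases = {d for _, d in plan.fold(i)}
                for j in range(i + 1, k):
                    assert not (diseases & {d for _, d in plan.fold(j)})


def test_by_pair_folds_partition_evenly():
    pairs = [(f"m{i}", f"d{i % 20}") for i in range(100)]
    plan = g.make_folds(pairs, k=10, grouping="by-pair", seed=1)
    sizes = [len(plan.fold(i)) for i in range(10)]
    assert sizes == [10] * 10
    assert sorted(p for i in range(10) for p in plan.fold(i)) == sorted(pairs)


def test_by_disease_folds_keep_diseases_together():
    pairs = [(f"m{j}", f"d{i}") for i in range(10) for j in range(5)]
    plan = g.make_folds(pairs, k=10, grouping="by-disease", seed=3)
    # 10 equal disease groups over 10 folds: one disease per fold
    for i in range(10):
        fold = plan.fold(i)
        assert len(fold) == 5
        assert len({d for _, d in fold}) == 1
    with pytest.raises(EvaluationError):
        g.make_folds(pairs, k=11, grouping="by-disease", seed=0)
    with pytest.raises(EvaluationError):
        g.make_folds([("m", "d"), ("m", "d")], k=2, grouping="by-pair", seed=0)


def test_report_recompute_roundtrip():
    rng = np.random.default_rng(2)
    fold_scores = []
    for _ in range(4):
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        fold_scores.append((y, rng.random(50)))
    rep = recompute_report(fold_scores, {"x": 1}, seed=0)
    rep2 = recompute_report(rep.fold_scores, {"x": 1}, seed=0)
    assert rep.per_fold == rep2.per_fold
    assert rep.mean == rep2.mean
    for key in ("auroc", "aupr"):
        assert min(f[key] for f in rep.per_fold) <= rep.mean[key] <= max(
            f[key] for f in rep.per_fold)
        assert rep.mean[key] == pytest.approx(
            np.mean([f[key] for f in rep.per_fold]))


# ---------------------------------------------------------------------------
# Pipeline-level checks on the tiny fixture
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_cfg():
    return g.RunConfig(embed_dim=8, encoder_epochs=4, epochs=4, folds=3,
                       batch_size=16, conv_filters=8, fc_hidden=16,
                       grouping="by-pair", seed=5)


def test_run_cv_schema_and_ranges(tiny_ds, tiny_cfg):
    rep = g.run_cv(tiny_ds.hetnet, tiny_ds.labels, tiny_cfg)
    assert len(rep.per_fold) == 3
    for fold in rep.per_fold:
        for key in ("auroc", "aupr", "precision", "recall", "f1"):
            assert np.isnan(fold[key]) or 0.0 <= fold[key] <= 1.0
    assert rep.config["folds"] == 3
    assert rep.seed == 5
    # recomputing from persisted fold scores reproduces the report exactly
    rep2 = recompute_report(rep.fold_scores, rep.config, rep.seed)
    for f1, f2 in zip(rep.per_fold, rep2.per_fold):
        for key in f1:
            assert f2[key] == pytest.approx(f1[key], abs=0, nan_ok=True)


def test_case_study_ranking_and_leakage_guard(tiny_ds, tiny_cfg):
    y = tiny_ds.labels
    counts = y.values.sum(axis=0)
    disease = y.disease_ids[int(np.argmax(counts))]
    res = g.case_study(tiny_ds.hetnet, y, disease, tiny_cfg)
    assert sorted(res.table["mirna"]) == sorted(y.mirna_ids)  # permutation
    assert not any(d == disease for _, d in res.train_pairs)  # leakage guard
    assert set(res.top_counts) == {10, 20, 30, 50}
    assert (res.table["score"].to_numpy()[:-1] >= res.table["score"].to_numpy()[1:]).all()
    with pytest.raises(EvaluationError):
        g.case_study(tiny_ds.hetnet, y, "not-a-disease", tiny_cfg)


def test_labels_are_never_graph_edges(tiny_ds):
    """Structural leakage guard: the encoder consumes dd/mm/gg/dg/mg only."""
    net = tiny_ds.hetnet
    label_pairs = set(tiny_ds.labels.positives())
    for etype, edges in net.edges.items():
        for a, b, _w in edges:
            assert (a, b) not in label_pairs and (b, a) not in label_pairs


def test_gene_overlap_baseline_range(tiny_ds):
    pos = tiny_ds.labels.positives()
    s = gene_overlap_baseline(tiny_ds.hetnet, pos)
    assert ((s >= 0) & (s <= 1)).all()
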