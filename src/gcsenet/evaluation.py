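"""Evaluation harness: negative sampling, grouped cross-validation,
classification metrics and the leave-one-disease-out case study.

Known miRNA-disease associations are positives; negatives are drawn
uniformly from unobserved cells of the association matrix at a chosen
neg:pos ratio (1:1 by default, with 10:1..100:1 robustness sweeps).
Cross-validation folds can group all of a disease's pairs into one fold
("by-disease", the default, preventing a disease's test pairs from
leaking into training through its other pairs) or split pairs freely
("by-pair").

Labels are never graph edges: the encoder sees only dd/mm/gg/dg/mg
structure, so held-out label pairs cannot reach training through the
network.  AUROC is the Mann-Whitney rank statistic (midrank ties) and
AUPR is average precision with step integration, both via scikit-learn;
the test suite cross-checks them against exhaustive pairwise oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import RunConfig
from .features import ChannelNormalizer, PairFeatureBuilder
from .gcn import encode, train_encoder
from .hetnet import AssociationMatrix, HetNet, NetworkError
from .senet import predict_proba, train_classifier

Pair = tuple[str, str]  # (mirna, disease)


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Sampling and fold construction
# ---------------------------------------------------------------------------

def sample_negatives(y: AssociationMatrix, ratio: float, seed: int) -> list[Pair]:
    """Uniform unobserved (miRNA, disease) cells, |neg| = round(ratio*|pos|)."""
    vals = y.values
    n_pos = int(vals.sum())
    if n_pos == 0:
        raise EvaluationError("association matrix has no positive entries")
    want = int(round(ratio * n_pos))
    zero_flat = np.flatnonzero(vals == 0)
    if want > zero_flat.size:
        max_ratio = zero_flat.size / n_pos
        raise EvaluationError(
            f"cannot sample {want} negatives from {zero_flat.size} unobserved "
            f"cells; maximum feasible ratio is {max_ratio:.2f}:1"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(zero_flat, size=want, replace=False)
    n_d = len(y.disease_ids)
    return [(y.mirna_ids[i // n_d], y.disease_ids[i % n_d]) for i in sorted(chosen)]


@dataclass(frozen=True)
class CVPlan:
    """Fold id (0..k-1) per labeled pair."""

    assignment: dict
    k: int
    grouping: str
    seed: int

    def fold(self, i: int) -> list[Pair]:
        return [p for p, f in self.assignment.items() if f == i]


def make_folds(pairs: list[Pair], k: int = 10, grouping: str = "by-disease",
               seed: int = 0) -> CVPlan:
    """Partition labeled pairs into k folds.

    by-disease: whole disease groups are dealt greedily (largest first)
    onto the currently smallest fold, so every pair of one disease shares
    a fold.  by-pair: a seeded shuffle dealt round-robin.
    """
    if k < 2:
        raise EvaluationError(f"need at least 2 folds, got {k}")
    if len(set(pairs)) != len(pairs):
        raise EvaluationError("duplicate pairs in fold request")
    rng = np.random.default_rng(seed)
    assignment: dict[Pair, int] = {}
    if grouping == "by-pair":
        order = list(pairs)
        rng.shuffle(order)
        for i, p in enumerate(order):
            assignment[p] = i % k
    elif grouping == "by-disease":
        groups: dict[str, list[Pair]] = {}
        for m, d in pairs:
            groups.setdefault(d, []).append((m, d))
        if len(groups) < k:
            raise EvaluationError(
                f"by-disease grouping needs >= {k} diseases, have {len(groups)}"
            )
        names = sorted(groups)
        rng.shuffle(names)
        names.sort(key=lambda d: -len(groups[d]))  # stable: keeps shuffle on ties
        sizes = np.zeros(k, dtype=int)
        for d in names:
            tgt = int(np.argmin(sizes))
            for p in groups[d]:
                assignment[p] = tgt
            sizes[tgt] += len(groups[d])
    else:
        raise EvaluationError(f"unknown grouping mode {grouping!r}")
    return CVPlan(assignment, k, grouping, seed)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_metrics(labels, scores, threshold: float = 0.5) -> dict:
    """Precision, recall and F1 at a probability threshold.

    Undefined ratios (no predicted positives / no actual positives) come
    back as NaN with a warning rather than a silent zero.
    """
    y = np.asarray(labels, dtype=int)
    pred = np.asarray(scores, dtype=float) >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    if tp + fp == 0:
        warnings.warn("no predicted positives; precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no actual positives; recall undefined", stacklevel=2)
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}


def auroc(labels, scores) -> float:
    """Area under the ROC curve (rank statistic with midrank ties)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUROC undefined with a single class")
    return float(roc_auc_score(y, scores))


def aupr(labels, scores) -> float:
    """Area under the precision-recall curve (average precision)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError("AUPR undefined with a single class")
    return float(average_precision_score(y, scores))


def fold_metrics(labels, scores, threshold: float = 0.5) -> dict:
    out = {"auroc": auroc(labels, scores), "aupr": aupr(labels, scores)}
    out.update(confusion_metrics(labels, scores, threshold))
    return out


METRIC_KEYS = ("auroc", "aupr", "precision", "recall", "f1")


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics plus everything needed to recompute them."""

    per_fold: list
    fold_scores: list          # (labels, scores) arrays per fold
    config: dict
    seed: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mean:
            for key in METRIC_KEYS:
                vals = np.array([f[key] for f in self.per_fold], dtype=float)
                self.mean[key] = float(np.nanmean(vals))
                self.sd[key] = float(np.nanstd(vals))

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "mean": self.mean,
            "sd": self.sd,
            "config": self.config,
            "seed": self.seed,
        }


def recompute_report(fold_scores, config: dict, seed: int,
                     threshold: float = 0.5) -> MetricsReport:
    """Rebuild a MetricsReport from persisted per-fold labels/scores."""
    per_fold = [fold_metrics(y, s, threshold) for y, s in fold_scores]
    return MetricsReport(per_fold, list(fold_scores), config, seed)


# ---------------------------------------------------------------------------
# Pipeline runs
# ---------------------------------------------------------------------------

def _fit_feature_builder(net: HetNet, config: RunConfig) -> PairFeatureBuilder:
    if config.no_gcn:
        return PairFeatureBuilder(
            net, None, None, config.alpha, weighting=not config.no_weighting,
            component=not config.no_component, use_gcn=False,
        )
    params, _trace = train_encoder(net, config)
    emb = encode(net, params)
    return PairFeatureBuilder(
        net, emb, params.decoders, config.alpha,
        weighting=not config.no_weighting, component=not config.no_component,
    )


def _train_and_score(builder: PairFeatureBuilder, train_pairs, train_labels,
                     test_pairs, config: RunConfig, seed: int) -> np.ndarray:
    norm = ChannelNormalizer()
    x_train = norm.fit_transform(builder.tensor(train_pairs))
    clf, _trace = train_classifier(x_train, train_labels, config, seed=seed)
    x_test = norm.transform(builder.tensor(test_pairs))
    return predict_proba(clf, x_test)


def run_cv(net: HetNet, y: AssociationMatrix, config: RunConfig) -> MetricsReport:
    """Full k-fold cross-validated pipeline evaluation.

    Negatives are sampled once at `config.neg_ratio`, folds built over
    all labeled pairs, and for each fold the classifier (and, when
    `encoder_per_fold` is set, the encoder) is trained on the remaining
    folds only; normalization statistics always come from the training
    folds.  The encoder consumes no labels, so by default it is fitted
    once on the graph and shared across folds.
    """
    positives = y.positives()
    negatives = sample_negatives(y, config.neg_ratio, config.seed)
    labels = {p: 1 for p in positives}
    labels.update({p: 0 for p in negatives})
    plan = make_folds(sorted(labels), config.folds, config.grouping, config.seed)
    builder = None if config.encoder_per_fold else _fit_feature_builder(net, config)
    per_fold, fold_scores = [], []
    for i in range(config.folds):
        test_pairs = sorted(plan.fold(i))
        train_pairs = sorted(p for p in labels if plan.assignment[p] != i)
        if not test_pairs or len({labels[p] for p in test_pairs}) < 2:
            warnings.warn(f"fold {i} lacks both classes; skipped", stacklevel=2)
            continue
        fold_builder = builder if builder is not None else _fit_feature_builder(net, config)
        y_train = np.array([labels[p] for p in train_pairs])
        y_test = np.array([labels[p] for p in test_pairs])
        scores = _train_and_score(
            fold_builder, train_pairs, y_train, test_pairs, config,
            seed=config.seed * 1000 + i,
        )
        per_fold.append(fold_metrics(y_test, scores, config.threshold))
        fold_scores.append((y_test, scores))
    if not per_fold:
        raise EvaluationError("no usable folds")
    return MetricsReport(per_fold, fold_scores, config.to_dict(), config.seed)


@dataclass
class CaseStudyResult:
    """Descending candidate ranking for one held-out disease."""

    disease: str
    table: pd.DataFrame        # columns: mirna, score, known
    top_counts: dict           # top-k -> number of known associations recovered
    train_pairs: list          # instrumentation: what the classifier saw


def case_study(net: HetNet, y: AssociationMatrix, disease: str,
               config: RunConfig) -> CaseStudyResult:
    """Leave-one-disease-out ranking of every candidate miRNA.

    All labeled pairs of the target disease are removed from classifier
    training (negatives are drawn from other diseases' columns too);
    every miRNA is then scored against the target and ranked.
    """
    if disease not in y.disease_ids:
        raise EvaluationError(f"unknown disease {disease!r}")
    known = {m for m, d in y.positives() if d == disease}
    if not known:
        raise EvaluationError(f"disease {disease!r} has no known miRNA associations")
    positives = [(m, d) for m, d in y.positives() if d != disease]
    negatives = [
        (m, d) for m, d in sample_negatives(y, config.neg_ratio, config.seed)
        if d != disease
    ]
    pos_set = set(positives)
    train_pairs = sorted(pos_set | set(negatives))
    train_labels = np.array([1 if p in pos_set else 0 for p in train_pairs])
    builder = _fit_feature_builder(net, config)
    candidates = sorted(y.mirna_ids)
    scores = _train_and_score(
        builder, train_pairs, train_labels,
        [(m, disease) for m in candidates], config, seed=config.seed,
    )
    table = pd.DataFrame({
        "mirna": candidates,
        "score": scores,
        "known": [m in known for m in candidates],
    }).sort_values(["score", "mirna"], ascending=[False, True]).reset_index(drop=True)
    top_counts = {k: int(table.head(k)["known"].sum()) for k in (10, 20, 30, 50)}
    return CaseStudyResult(disease, table, top_counts, train_pairs)


# ---------------------------------------------------------------------------
# Reference baseline
# ---------------------------------------------------------------------------

def gene_overlap_baseline(net: HetNet, pairs: list[Pair]) -> np.ndarray:
    """Cosine overlap of a pair's gene neighbourhoods; no learning involved.

    score(m, d) = |G(d) & G(m)| / sqrt(|G(d)| * |G(m)|) over the dg/mg
    edge sets — the degree-aware association strength any gene-mediated
    model must beat to justify its machinery.
    """
    d_genes: dict[str, set] = {}
    m_genes: dict[str, set] = {}
    for a, b, _w in net.edges.get("dg", ()):
        d_genes.setdefault(a, set()).add(b)
    for a, b, _w in net.edges.get("mg", ()):
        m_genes.setdefault(a, set()).add(b)
    out = np.zeros(len(pairs))
    for i, (m, d) in enumerate(pairs):
        gd, gm = d_genes.get(d, set()), m_genes.get(m, set())
        if gd and gm:
            out[i] = len(gd & gm) / np.sqrt(len(gd) * len(gm))
    return out
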