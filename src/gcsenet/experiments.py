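"""Higher-level evaluation protocols built on the CV harness.

These drive the robustness analyses around the core pipeline: ablation
comparisons (drop the GCN, the degree weighting, the combined channel or
the SE block, one at a time), negative-ratio sweeps, and label-shuffle
null controls.  They share one encoder fit per dataset/seed where the
protocol permits it — the encoder never consumes labels, so variants and
shuffles that only change the classifier's labels can reuse it.

Epoch counts scale down with training-set size in the sweep protocols so
a whole suite stays in CPU-minutes territory; the single-run CV entry
point `evaluation.run_cv` is the place for full-strength settings.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .config import RunConfig
from .evaluation import (
    _fit_feature_builder,
    _train_and_score,
    auroc,
    sample_negatives,
)
from .features import PairFeatureBuilder
from .hetnet import AssociationMatrix, HetNet
from .synthetic import SyntheticDataset

ABLATIONS = ("no_gcn", "no_weighting", "no_component", "no_senet")


def _labeled_pairs(y: AssociationMatrix, ratio: float, seed: int):
    positives = y.positives()
    negatives = sample_negatives(y, ratio, seed)
    pairs = sorted(set(positives) | set(negatives))
    pos_set = set(positives)
    labels = np.array([1 if p in pos_set else 0 for p in pairs])
    return pairs, labels


def split_eval_auroc(
    builder: PairFeatureBuilder,
    pairs: list,
    labels: np.ndarray,
    config: RunConfig,
    seed: int,
    test_frac: float = 0.2,
) -> float:
    """AUROC of one stratified train/test split of the labeled pairs."""
    idx = np.arange(len(pairs))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, stratify=labels, random_state=seed % (2**32)
    )
    scores = _train_and_score(
        builder,
        [pairs[i] for i in train_idx], labels[train_idx],
        [pairs[i] for i in test_idx], config, seed,
    )
    return auroc(labels[test_idx], scores)


def _variant_builder(net: HetNet, config: RunConfig, shared) -> PairFeatureBuilder:
    """Feature builder for an ablation config, reusing a fitted encoder."""
    if config.no_gcn:
        return PairFeatureBuilder(
            net, None, None, config.alpha, weighting=not config.no_weighting,
            component=not config.no_component, use_gcn=False,
        )
    emb, decoders = shared
    return PairFeatureBuilder(
        net, emb, decoders, config.alpha,
        weighting=not config.no_weighting, component=not config.no_component,
    )


def ablation_suite(
    ds: SyntheticDataset,
    config: RunConfig,
    seeds: tuple = (0, 1, 2, 3, 4),
) -> dict[str, list[float]]:
    """Split-evaluation AUROC per seed for the full model and each ablation.

    Per seed: one negative sample, one stratified 80/20 split, one encoder
    fit shared by every embedding-based variant.
    """
    from .gcn import encode, train_encoder

    out: dict[str, list[float]] = {"full": []}
    out.update({a: [] for a in ABLATIONS})
    for seed in seeds:
        cfg = config.replace(seed=int(seed))
        pairs, labels = _labeled_pairs(ds.labels, cfg.neg_ratio, cfg.seed)
        params, _ = train_encoder(ds.hetnet, cfg)
        shared = (encode(ds.hetnet, params), params.decoders)
        for name in ("full", *ABLATIONS):
            vcfg = cfg if name == "full" else cfg.replace(**{name: True})
            builder = _variant_builder(ds.hetnet, vcfg, shared)
            out[name].append(split_eval_auroc(builder, pairs, labels, vcfg, cfg.seed))
    return out


def _scaled_epochs(config: RunConfig, n_pairs: int, reference: int = 600) -> RunConfig:
    """Shrink epochs (and grow batches) as the labeled set grows.

    Keeps the number of gradient steps of the same order as a reference
    1:1 run so highly imbalanced sweeps stay tractable.
    """
    epochs = max(12, int(round(config.epochs * reference / max(n_pairs, 1))))
    batch = config.batch_size if n_pairs <= 4 * reference else 4 * config.batch_size
    return config.replace(epochs=epochs, batch_size=batch)


def ratio_sweep(
    ds: SyntheticDataset,
    config: RunConfig,
    ratios: tuple = (1, 10, 20, 50, 100),
    seed: int = 0,
) -> dict[float, float]:
    """AUROC on one fixed test set while the TRAINING neg:pos ratio varies.

    All ratios are scored on the same held-out 1:1 test split so the
    numbers differ only through what the classifier was trained on.  A
    finite label grid bounds the achievable ratio: when ratio * n_pos
    exceeds the free cells, a seeded subsample of training positives is
    used so the requested class ratio is realised exactly.
    """
    cfg0 = config.replace(seed=int(seed))
    builder = _fit_feature_builder(ds.hetnet, cfg0)
    rng = np.random.default_rng(cfg0.seed)

    positives = ds.labels.positives()
    n_pos = len(positives)
    order = rng.permutation(n_pos)
    n_test = max(int(round(0.2 * n_pos)), 1)
    test_pos = [positives[i] for i in order[:n_test]]
    train_pos_all = [positives[i] for i in order[n_test:]]

    # negatives: one shared pool, disjoint from positives; the first slice
    # is the fixed test negatives, the rest feeds the training sets
    max_ratio = max(ratios)
    free = ds.labels.values.size - n_pos
    pool = sample_negatives(ds.labels, free / n_pos, cfg0.seed)  # all free cells
    rng.shuffle(pool)
    test_neg, train_pool = pool[:n_test], pool[n_test:]
    test_pairs = sorted(set(test_pos) | set(test_neg))
    test_labels = np.array([1 if p in set(test_pos) else 0 for p in test_pairs])

    out: dict[float, float] = {}
    for ratio in ratios:
        ratio = float(ratio)
        train_pos = train_pos_all
        want_neg = int(round(ratio * len(train_pos)))
        if want_neg > len(train_pool):
            # shrink positives so the grid supports the exact ratio
            keep = int(len(train_pool) // ratio)
            if keep < 1:
                raise ValueError(f"grid cannot realise a {ratio}:1 training ratio")
            train_pos = train_pos_all[:keep]
            want_neg = int(round(ratio * keep))
        train_pairs = sorted(set(train_pos) | set(train_pool[:want_neg]))
        labels = np.array([1 if p in set(train_pos) else 0 for p in train_pairs])
        cfg = _scaled_epochs(cfg0.replace(neg_ratio=ratio), len(train_pairs))
        scores = _train_and_score(builder, train_pairs, labels, test_pairs, cfg, cfg.seed)
        out[ratio] = auroc(test_labels, scores)
    return out


def shuffled_labels(y: AssociationMatrix, seed: int) -> AssociationMatrix:
    """Same number of positives placed uniformly at random (null labels)."""
    rng = np.random.default_rng(seed)
    n_pos = int(y.values.sum())
    flat = rng.choice(y.values.size, size=n_pos, replace=False)
    vals = np.zeros(y.values.size, dtype=np.int8)
    vals[flat] = 1
    return AssociationMatrix(y.mirna_ids, y.disease_ids, vals.reshape(y.values.shape))


def shuffled_control(
    ds: SyntheticDataset,
    config: RunConfig,
    seeds: tuple = (0, 1, 2, 3, 4),
) -> list[float]:
    """Mean split AUROC per seed when labels carry no signal.

    The encoder is fitted once (it never sees labels); each seed gets a
    fresh uniform relabelling, negative sample and split.
    """
    builder = _fit_feature_builder(ds.hetnet, config)
    out = []
    for seed in seeds:
        cfg = config.replace(seed=int(seed))
        y_null = shuffled_labels(ds.labels, 7_000_000 + seed)
        pairs, labels = _labeled_pairs(y_null, cfg.neg_ratio, cfg.seed)
        out.append(split_eval_auroc(builder, pairs, labels, cfg, cfg.seed,
                                    test_frac=0.5))
    return out


def baseline_auroc(ds: SyntheticDataset, seed: int, ratio: float = 1.0) -> float:
    """Gene-overlap baseline AUROC on the same labeled pairs the model sees."""
    from .evaluation import gene_overlap_baseline

    pairs, labels = _labeled_pairs(ds.labels, ratio, seed)
    return auroc(labels, gene_overlap_baseline(ds.hetnet, pairs))
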