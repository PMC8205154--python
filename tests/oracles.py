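"""Independent brute-force oracles shared by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration (paths, pairs,
edges, thresholds) with no code shared with the implementation it
checks.
"""

import numpy as np

from gcsenet.gcn import RELATIONS
from gcsenet.ontology import TermDAG

NODE_TYPES = ("disease", "gene", "mirna")


def contributions_oracle(dag: TermDAG, target: str, delta: float) -> dict:
    """Enumerate every upward path from target; score delta**len; keep max."""
    best = {target: 1.0}

    def walk(term, length):
        for p in dag.parents(term):
            score = delta ** (length + 1)
            if score > best.get(p, 0.0):
                best[p] = score
            walk(p, length + 1)

    walk(target, 0)
    return best


def similarity_oracle(dag, t1, t2, delta):
    c1 = contributions_oracle(dag, t1, delta)
    c2 = contributions_oracle(dag, t2, delta)
    shared = c1.keys() & c2.keys()
    if not shared:
        return 0.0
    return sum(c1[t] + c2[t] for t in shared) / (sum(c1.values()) + sum(c2.values()))


def closure_oracle(dag: TermDAG, direct: dict, term: str) -> set:
    """Transitive-closure union of direct annotations over descendants."""
    acc = set(direct.get(term, ()))
    for c in dag.children(term):
        acc |= closure_oracle(dag, direct, c)
    return acc



def dense_layer_oracle(net, h, layer):
    """Edge-by-edge recomputation of one relational convolution step.

    Walks every edge explicitly (no matrix algebra shared with the
    implementation) applying c_ij * w_ij * W_l z_j + scaled self term,
    then ReLU.
    """
    ids = {"disease": net.diseases, "gene": net.genes, "mirna": net.mirnas}
    idx = {t: {x: i for i, x in enumerate(ids[t])} for t in ids}
    # per-relation neighbour counts (self-inclusive for within-type)
    deg = {r: {} for r in RELATIONS}
    within = {"dd": "disease", "gg": "gene", "mm": "mirna"}
    for etype, t in within.items():
        for x in ids[t]:
            deg[etype][x] = 1.0
        for a, b, _w in net.edges[etype]:
            deg[etype][a] += 1
            deg[etype][b] += 1
    for etype, fwd, bwd in (("dg", "dg", "gd"), ("mg", "mg", "gm")):
        ta = "disease" if etype == "dg" else "mirna"
        deg[fwd] = {x: 0.0 for x in ids[ta]}
        deg[bwd] = {x: 0.0 for x in ids["gene"]}
        for a, b, _w in net.edges[etype]:
            deg[fwd][a] += 1
            deg[bwd][b] += 1
    etype_of = {v: k for k, v in within.items()}
    out = {}
    for t in NODE_TYPES:
        n = len(ids[t])
        res = np.zeros((n, layer["self"][t].data.shape[0]))
        dcoef = deg[etype_of[t]]
        for i, x in enumerate(ids[t]):
            res[i] = (1.0 / dcoef[x]) * (layer["self"][t].data @ h[t][i])
        out[t] = res

    def add_msg(dst_t, src_t, rel, a, b, w, da, db):
        i, j = idx[dst_t][a], idx[src_t][b]
        c = 1.0 / np.sqrt(da * db)
        out[dst_t][i] += c * w * (layer["rel"][rel].data @ h[src_t][j])

    for etype, t in within.items():
        for a, b, w in net.edges[etype]:
            add_msg(t, t, etype, a, b, w, deg[etype][a], deg[etype][b])
            add_msg(t, t, etype, b, a, w, deg[etype][b], deg[etype][a])
    for a, b, w in net.edges["dg"]:
        add_msg("disease", "gene", "dg", a, b, w, deg["dg"][a], deg["gd"][b])
        add_msg("gene", "disease", "gd", b, a, w, deg["gd"][b], deg["dg"][a])
    for a, b, w in net.edges["mg"]:
        add_msg("mirna", "gene", "mg", a, b, w, deg["mg"][a], deg["gm"][b])
        add_msg("gene", "mirna", "gm", b, a, w, deg["gm"][b], deg["mg"][a])
    return {t: np.maximum(v, 0.0) for t, v in out.items()}



def auroc_oracle(labels, scores):
    """P(score_pos > score_neg) + 0.5 P(tie) over all pos x neg pairs."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def aupr_oracle(labels, scores):
    """Average precision by explicit threshold sweep (step integration)."""
    labels, scores = np.asarray(labels), np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    labels, scores = labels[order], scores[order]
    n_pos = labels.sum()
    ap, tp, prev_recall = 0.0, 0, 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:  # whole tie block
            j += 1
        tp += labels[i:j].sum()
        recall = tp / n_pos
        precision = tp / j
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def confusion_oracle(labels, scores, thr=0.5):
    tp = sum(1 for y, s in zip(labels, scores) if y == 1 and s >= thr)
    fp = sum(1 for y, s in zip(labels, scores) if y == 0 and s >= thr)
    fn = sum(1 for y, s in zip(labels, scores) if y == 1 and s < thr)
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return p, r, 2 * p * r / (p + r)


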