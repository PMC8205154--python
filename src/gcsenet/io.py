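"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with a required header row.  Schemas:

* edge list:    ``source<TAB>target[<TAB>weight]`` (missing weight = 1.0)
* term DAG:     ``child<TAB>parent``
* annotations:  ``term<TAB>gene``
* labels:       ``mirna<TAB>disease<TAB>label`` with label in {0, 1}
* scores:       ``mirna<TAB>disease<TAB>score`` sorted descending
* similarity:   square matrix with id header row and id first column

Malformed rows are reported with 1-based line numbers (header = line 1).
Writes are atomic: a temp file in the target directory is renamed over
the destination.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .hetnet import AssociationMatrix
from .ontology import SimilarityMatrix, TermDAG


class FormatError(ValueError):
    pass


def _read_tsv(path, min_cols: int, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{what} file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < min_cols:
        raise FormatError(
            f"{path}: {what} needs >= {min_cols} columns, found {df.shape[1]} "
            f"(is the header line present?)"
        )
    return df


def _atomic_write(path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edge_tsv(path) -> list[tuple[str, str, float]]:
    df = _read_tsv(path, 2, "edge list")
    out, seen = [], set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        a, b = str(row[0]), str(row[1])
        if df.shape[1] >= 3 and str(row[2]) != "":
            try:
                w = float(row[2])
            except ValueError:
                raise FormatError(f"{path}:{i}: non-numeric weight {row[2]!r}")
        else:
            w = 1.0
        if (a, b) in seen:
            warnings.warn(f"{path}:{i}: duplicate edge ({a}, {b}); keeping first",
                          stacklevel=2)
            continue
        seen.add((a, b))
        out.append((a, b, w))
    return out


def write_edge_tsv(path, edges, header=("source", "target", "weight")) -> None:
    def _w(fh):
        fh.write("\t".join(header) + "\n")
        for a, b, w in sorted(edges):
            fh.write(f"{a}\t{b}\t{w:.17g}\n")

    _atomic_write(path, _w)


# ---------------------------------------------------------------------------
# DAG / annotations / labels
# ---------------------------------------------------------------------------

def read_dag_tsv(path) -> TermDAG:
    df = _read_tsv(path, 2, "term hierarchy")
    return TermDAG.from_edges([(str(r[0]), str(r[1]))
                               for r in df.itertuples(index=False)])


def write_dag_tsv(path, dag: TermDAG) -> None:
    def _w(fh):
        fh.write("child\tparent\n")
        for c, p in sorted(dag.edges):
            fh.write(f"{c}\t{p}\n")

    _atomic_write(path, _w)


def read_annotations_tsv(path) -> dict[str, set[str]]:
    df = _read_tsv(path, 2, "annotation")
    out: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r[0]), set()).add(str(r[1]))
    return out


def write_annotations_tsv(path, direct: dict) -> None:
    def _w(fh):
        fh.write("term\tgene\n")
        for t in sorted(direct):
            for g in sorted(direct[t]):
                fh.write(f"{t}\t{g}\n")

    _atomic_write(path, _w)


def read_labels_tsv(path, mirna_ids=None, disease_ids=None) -> AssociationMatrix:
    """Load a long-format label table.

    The table lists known pairs only, so the candidate grid cannot be
    inferred from it alone: pass the network's miRNA/disease registries
    so unlisted cells count as unobserved candidates rather than
    disappearing from the matrix.
    """
    df = _read_tsv(path, 3, "label table")
    pairs = []
    for i, r in enumerate(df.itertuples(index=False), start=2):
        try:
            lab = int(r[2])
        except ValueError:
            lab = -1
        if lab not in (0, 1):
            raise FormatError(f"{path}:{i}: label must be 0 or 1, got {r[2]!r}")
        pairs.append((str(r[0]), str(r[1]), lab))
    if mirna_ids is not None:
        known_m, known_d = set(mirna_ids), set(disease_ids)
        for m, d, _lab in pairs:
            if m not in known_m or d not in known_d:
                raise FormatError(
                    f"{path}: label pair ({m}, {d}) references an id outside "
                    f"the network registries"
                )
    return AssociationMatrix.from_pairs(pairs, mirna_ids, disease_ids)


def write_labels_tsv(path, y: AssociationMatrix) -> None:
    def _w(fh):
        fh.write("mirna\tdisease\tlabel\n")
        for m, d in y.positives():
            fh.write(f"{m}\t{d}\t1\n")

    _atomic_write(path, _w)


# ---------------------------------------------------------------------------
# Similarity matrices / scores / metrics
# ---------------------------------------------------------------------------

def read_similarity_tsv(path) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    ids = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != ids:
        raise FormatError(f"{path}: similarity row ids must equal column ids")
    return SimilarityMatrix(ids, df.to_numpy(dtype=float))


def write_similarity_tsv(path, sim: SimilarityMatrix) -> None:
    def _w(fh):
        fh.write("id\t" + "\t".join(sim.ids) + "\n")
        for i, a in enumerate(sim.ids):
            fh.write(a + "\t" + "\t".join(f"{v:.17g}" for v in sim.values[i]) + "\n")

    _atomic_write(path, _w)


def write_scores_tsv(path, rows) -> None:
    """rows: iterable of (mirna, disease, score); written score-descending."""

    def _w(fh):
        fh.write("mirna\tdisease\tscore\n")
        for m, d, s in sorted(rows, key=lambda r: (-float(r[2]), r[0], r[1])):
            fh.write(f"{m}\t{d}\t{float(s):.17g}\n")

    _atomic_write(path, _w)


def read_scores_tsv(path) -> list[tuple[str, str, float]]:
    df = _read_tsv(path, 3, "score table")
    return [(str(r[0]), str(r[1]), float(r[2])) for r in df.itertuples(index=False)]


def write_metrics_json(path, report: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    _atomic_write(path, lambda fh: json.dump(report, fh, indent=2, default=_default))


# ---------------------------------------------------------------------------
# Whole-dataset round trip (synthetic fixtures, CLI `simulate`)
# ---------------------------------------------------------------------------

def write_dataset(ds, outdir) -> None:
    """Write every table of a SyntheticDataset plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = ds.hetnet
    for etype in ("gg", "dg", "mg"):
        write_edge_tsv(outdir / f"{etype}_edges.tsv",
                       sorted(net.edges.get(etype, ())))
    for etype in ("dd", "mm"):
        write_edge_tsv(outdir / f"{etype}_edges.tsv",
                       sorted(net.edges.get(etype, ())))
    write_dag_tsv(outdir / "disease_dag.tsv", ds.dag)
    write_annotations_tsv(outdir / "annotations.tsv",
                          {t: set(g) for t, g in ds.annotations.direct.items()})
    write_labels_tsv(outdir / "labels.tsv", ds.labels)
    manifest = {"seed": ds.seed, "params": ds.params,
                "n_nodes": {"disease": len(net.diseases), "gene": len(net.genes),
                            "mirna": len(net.mirnas)},
                "n_edges": {k: len(v) for k, v in net.edges.items()}}
    write_metrics_json(outdir / "manifest.json", manifest)


def read_dataset_edges(indir) -> dict:
    """Load the five edge tables written by `write_dataset`."""
    indir = Path(indir)
    return {etype: read_edge_tsv(indir / f"{etype}_edges.tsv")
            for etype in ("dd", "mm", "gg", "dg", "mg")}
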