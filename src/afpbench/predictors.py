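"""Built-in function predictors and the external score-table plug-in path.

Three simple predictors cover the in-scope methods:

* **guilt-by-association (GBA)** — neighbour voting: the confidence for
  (protein, term) is the fraction of the protein's direct network
  neighbours annotated with the term in the training set;
* **node-degree classifier** — a diagnostic baseline that scores every term
  with the protein's (max-normalised) network degree, probing how much of a
  method's apparent accuracy is explained by multifunctionality alone;
* **kernel k-nearest-neighbour** — the fraction of a protein's k most
  kernel-similar training proteins annotated with the term; a light-weight
  stand-in for per-term supervised classifiers over the same kernels.

Predictions produced by any external method (structured SVMs, binary SVMs,
...) are evaluated through :func:`load_external_scores`, which reads the
3-column protein/term/score exchange format.
"""

from __future__ import annotations

import warnings
from typing import Collection, Sequence

import numpy as np
import pandas as pd

from .features import KernelMatrix
from .ontology import AnnotationSet, OntologyDAG, ScoreTable

__all__ = [
    "ScoreTable",
    "gba_predict",
    "node_degree_predict",
    "kernel_knn_score",
    "load_external_scores",
    "kernel_to_adjacency",
]


def kernel_to_adjacency(kernel: KernelMatrix, threshold: float = 0.0) -> pd.DataFrame:
    """Binarise a kernel into an undirected network.

    An edge joins two distinct proteins when their kernel value is strictly
    greater than *threshold* (default 0: any positive similarity).  The
    diagonal is cleared, so a protein is never its own neighbour.
    """
    adjacency = (kernel.values > threshold).astype(int)
    np.fill_diagonal(adjacency, 0)
    return pd.DataFrame(adjacency, index=kernel.proteins, columns=kernel.proteins)


def _as_adjacency(network) -> pd.DataFrame:
    if isinstance(network, KernelMatrix):
        return kernel_to_adjacency(network)
    adjacency = pd.DataFrame(network)
    if not adjacency.index.equals(adjacency.columns):
        raise ValueError("adjacency frame must have identical row/column labels")
    return adjacency


def _label_matrix(
    train_annotations: AnnotationSet, proteins: Sequence[str], terms: Sequence[str]
) -> np.ndarray:
    pairs = train_annotations.pairs()
    labels = np.zeros((len(proteins), len(terms)))
    term_index = {t: j for j, t in enumerate(terms)}
    protein_index = {p: i for i, p in enumerate(proteins)}
    for protein, term in pairs:
        i = protein_index.get(protein)
        j = term_index.get(term)
        if i is not None and j is not None:
            labels[i, j] = 1.0
    return labels


def gba_predict(
    network,
    train_annotations: AnnotationSet,
    test_proteins: Sequence[str],
    terms: Collection[str],
) -> ScoreTable:
    """Neighbour-voting guilt-by-association scores.

    ``score(p, j)`` is the fraction of p's direct neighbours carrying term j
    in the propagated training set.  Only the training annotation state is
    consulted; a test protein's own annotations never contribute.  Proteins
    with no neighbours — or absent from the network altogether — score 0
    everywhere (the latter with a warning, as uncovered targets).

    *network* is either a :class:`~afpbench.features.KernelMatrix`
    (binarised via :func:`kernel_to_adjacency`) or a square 0/1 adjacency
    frame labelled by protein.
    """
    if not train_annotations.propagated:
        raise ValueError("GBA requires propagated training annotations")
    adjacency = _as_adjacency(network)
    nodes = list(adjacency.index)
    terms = sorted(terms)
    labels = _label_matrix(train_annotations, nodes, terms)
    a = adjacency.to_numpy(dtype=float)
    degree = a.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fractions = (a @ labels) / degree[:, None]
    fractions[degree == 0] = 0.0

    node_index = {p: i for i, p in enumerate(nodes)}
    out = np.zeros((len(test_proteins), len(terms)))
    missing = []
    for row, protein in enumerate(test_proteins):
        i = node_index.get(protein)
        if i is None:
            missing.append(protein)
            continue
        out[row] = fractions[i]
    if missing:
        warnings.warn(
            f"{len(missing)} test protein(s) absent from the network scored 0"
        )
    return ScoreTable(pd.DataFrame(out, index=list(test_proteins), columns=terms))


def node_degree_predict(
    network,
    test_proteins: Sequence[str],
    terms: Collection[str],
) -> ScoreTable:
    """Score every term with the protein's network degree.

    Degrees are rescaled to [0, 1] by the maximum degree in the network so
    the result is a valid confidence table; rank-based metrics (AUC, F-max
    threshold sweeps) are unaffected by the rescaling.  An empty network
    yields all-zero scores with a warning.
    """
    adjacency = _as_adjacency(network)
    degree = adjacency.to_numpy(dtype=float).sum(axis=1)
    max_degree = degree.max(initial=0.0)
    if max_degree == 0:
        warnings.warn("network has no edges; node-degree scores are all zero")
        scaled = pd.Series(0.0, index=adjacency.index)
    else:
        scaled = pd.Series(degree / max_degree, index=adjacency.index)
    terms = sorted(terms)
    column = np.array([scaled.get(p, 0.0) for p in test_proteins])
    values = np.repeat(column[:, None], len(terms), axis=1)
    return ScoreTable(pd.DataFrame(values, index=list(test_proteins), columns=terms))


def kernel_knn_score(
    kernel: KernelMatrix,
    train_annotations: AnnotationSet,
    test_proteins: Sequence[str],
    terms: Collection[str],
    k: int = 10,
) -> ScoreTable:
    """k-nearest-neighbour voting in kernel space.

    ``score(p, j)`` is the fraction of p's *k* most kernel-similar training
    proteins annotated with term j.  Similarity ties are broken by the
    training proteins' position in the kernel ordering (stable).  A test
    protein that is itself a training protein never votes for itself.  If
    *k* exceeds the training set it is clamped with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not train_annotations.propagated:
        raise ValueError("kNN requires propagated training annotations")
    train_proteins = [p for p in kernel.proteins if p in train_annotations.proteins]
    if not train_proteins:
        raise ValueError("no training proteins present in the kernel")
    if k > len(train_proteins):
        warnings.warn(
            f"k={k} exceeds {len(train_proteins)} training proteins; clamped"
        )
        k = len(train_proteins)
    terms = sorted(terms)
    labels = _label_matrix(train_annotations, train_proteins, terms)
    kernel_index = {p: i for i, p in enumerate(kernel.proteins)}
    train_cols = np.array([kernel_index[p] for p in train_proteins])

    out = np.zeros((len(test_proteins), len(terms)))
    for row, protein in enumerate(test_proteins):
        i = kernel_index.get(protein)
        if i is None:
            warnings.warn(f"test protein {protein!r} absent from the kernel; scored 0")
            continue
        sims = kernel.values[i, train_cols].astype(float)
        eligible = np.array([p != protein for p in train_proteins])
        order = np.argsort(-sims, kind="stable")
        chosen = [j for j in order if eligible[j]][:k]
        if chosen:
            out[row] = labels[chosen].mean(axis=0)
    return ScoreTable(pd.DataFrame(out, index=list(test_proteins), columns=terms))


def load_external_scores(path, dag: OntologyDAG) -> tuple[ScoreTable, int]:
    """Read a 3-column (protein, term, score) prediction file.

    Scores are clipped into [0, 1]; rows naming terms unknown to the
    ontology are dropped and counted (the count is returned alongside the
    table).  Duplicate (protein, term) rows keep the maximum score, which is
    consistent with upward propagation semantics.  Malformed rows raise with
    their line number.  Propagation is *not* applied here — the evaluation
    layer propagates defensively.
    """
    rows: list[tuple[str, str, float]] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            protein, term, raw = fields
            try:
                score = float(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: bad score {raw!r}"
                ) from exc
            if term not in dag:
                dropped += 1
                continue
            rows.append((protein, term, min(max(score, 0.0), 1.0)))
    if dropped:
        warnings.warn(f"{path}: dropped {dropped} row(s) with unknown terms")
    if not rows:
        return ScoreTable(pd.DataFrame()), dropped
    return ScoreTable.from_long(rows), dropped
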