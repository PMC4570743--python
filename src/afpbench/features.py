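"""Feature encodings and kernels for function prediction.

Covers the per-protein representations a multi-source predictor consumes:

* **e-max homology features** — for protein ``s`` and category ``j``,
  ``max over s' annotated with j of -log(e(s, s') / 10)`` where ``e`` is a
  pairwise alignment e-value; a simplified GOtcha-style homology transfer
  score.
* **low-complexity features** — the amino-acid composition of the length-20
  window with the fewest distinct residues.
* **network adjacency features** — binary interaction indicator vectors over
  a fixed protein universe; multiple networks concatenate.
* **kernels** — linear kernels over feature blocks, cosine normalisation
  ``K(z1,z2)/sqrt(K(z1,z1) K(z2,z2))`` and multi-source combination by
  entrywise addition of normalised kernels.

Side-channel features computed by external tools (subcellular localisation,
transmembrane-domain counts, literature co-mention counts) enter as plain
tables; no external program is executed here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import AnnotationSet

__all__ = [
    "AMINO_ACIDS",
    "SimilarityTable",
    "KernelMatrix",
    "emax_features",
    "low_complexity_features",
    "network_adjacency_features",
    "linear_kernel",
    "normalize_kernel",
    "combine_kernels",
    "read_similarity_tsv",
    "read_edge_list",
    "read_fasta",
    "read_feature_table",
]

#: The 20 standard residues, in the column order of composition vectors.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Floor applied to e-values of 0 reported by aligners, before the log.
EVALUE_FLOOR = 1e-180


# ---------------------------------------------------------------------------
# Similarity tables and e-max
# ---------------------------------------------------------------------------


@dataclass
class SimilarityTable:
    """Pairwise alignment e-values: ``hits[query][subject] = e-value``.

    E-values are dimensionless and strictly positive; a missing pair means
    no reported hit.
    """

    hits: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for query, subjects in self.hits.items():
            for subject, evalue in subjects.items():
                if evalue <= 0:
                    raise ValueError(
                        f"non-positive e-value {evalue!r} for ({query!r}, {subject!r})"
                    )

    def evalue(self, query: str, subject: str) -> float | None:
        return self.hits.get(query, {}).get(subject)

    @property
    def queries(self) -> frozenset[str]:
        return frozenset(self.hits)


def emax_features(
    sim: SimilarityTable,
    train_annotations: AnnotationSet,
    divisor: float = 10.0,
    floor: float = EVALUE_FLOOR,
) -> pd.DataFrame:
    """Homology-transfer features: e-max score per (query protein, term).

    For query ``s`` and term ``j`` with training protein set ``S_j``:
    ``emax_j(s) = max over s' in S_j of -log10(e(s, s') / divisor)``,
    where only subjects with a reported hit contribute.  No hit to any
    member of ``S_j`` gives 0, and negative values (very weak hits) are
    clamped to 0 so features stay non-negative.  *train_annotations* must be
    propagated so that ``S_j`` respects the true path rule.

    Returns a frame indexed by query protein with one column per term.
    """
    if not train_annotations.propagated:
        raise ValueError("e-max requires propagated training annotations")
    term_proteins = train_annotations.term_to_proteins()
    queries = sorted(sim.queries)
    terms = sorted(term_proteins)
    out = np.zeros((len(queries), len(terms)))
    for i, query in enumerate(queries):
        hits = sim.hits.get(query, {})
        if not hits:
            continue
        scored = {
            subject: -math.log10(max(evalue, floor) / divisor)
            for subject, evalue in hits.items()
        }
        for j, term in enumerate(terms):
            best = max(
                (scored[s] for s in term_proteins[term] if s in scored),
                default=0.0,
            )
            out[i, j] = max(best, 0.0)
    return pd.DataFrame(out, index=queries, columns=terms)


# ---------------------------------------------------------------------------
# Sequence features
# ---------------------------------------------------------------------------


def low_complexity_features(sequence: str, window: int = 20) -> np.ndarray:
    """Composition of the lowest-complexity window of a protein sequence.

    Scans every contiguous window of the given length, selects the one with
    the fewest *distinct* residues (ties broken leftmost), and returns its
    amino-acid composition as a length-20 vector of fractions (order
    :data:`AMINO_ACIDS`) summing to 1.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    if len(sequence) < window:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than window {window}"
        )
    best_start, best_distinct = 0, window + 1
    for start in range(len(sequence) - window + 1):
        distinct = len(set(sequence[start : start + window]))
        if distinct < best_distinct:
            best_start, best_distinct = start, distinct
    chosen = sequence[best_start : best_start + window]
    counts = np.array([chosen.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return counts / window


# ---------------------------------------------------------------------------
# Network features
# ---------------------------------------------------------------------------


def network_adjacency_features(
    edges: Iterable[tuple[str, str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Binary interaction vectors over a fixed protein universe.

    Component i of protein p is 1 iff {p, universe[i]} is an (undirected)
    edge; self-components are 0 unless a self-loop is listed.  Edges with an
    endpoint outside the universe are dropped with a warning.  Concatenate
    frames from several networks for a multi-network representation; taking
    the union of two edge lists is equivalent to the entrywise OR of their
    encodings.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("protein universe is empty")
    index = {p: i for i, p in enumerate(universe)}
    matrix = np.zeros((len(universe), len(universe)), dtype=int)
    dropped = 0
    for a, b in edges:
        if a not in index or b not in index:
            dropped += 1
            continue
        matrix[index[a], index[b]] = 1
        matrix[index[b], index[a]] = 1
    if dropped:
        warnings.warn(f"dropped {dropped} edge(s) with endpoints outside the universe")
    return pd.DataFrame(matrix, index=universe, columns=universe)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


@dataclass
class KernelMatrix:
    """A symmetric pairwise kernel over an ordered protein list."""

    proteins: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        values = np.asarray(self.values, dtype=float)
        n = len(self.proteins)
        if values.shape != (n, n):
            raise ValueError(f"kernel shape {values.shape} does not match {n} proteins")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("kernel matrix is not symmetric")
        self.values = values

    def index_of(self, protein: str) -> int:
        return self.proteins.index(protein)


def linear_kernel(features: pd.DataFrame) -> KernelMatrix:
    """Linear kernel X X^T over a (protein x feature) frame."""
    x = features.to_numpy(dtype=float)
    return KernelMatrix(tuple(features.index), x @ x.T)


def normalize_kernel(kernel: KernelMatrix) -> KernelMatrix:
    """Cosine-normalise: K'(z1,z2) = K(z1,z2) / sqrt(K(z1,z1) K(z2,z2)).

    The diagonal becomes exactly 1; symmetry is preserved and entries of a
    positive-semidefinite input stay in [-1, 1].  Idempotent.  Raises on a
    zero or negative diagonal, naming the offending protein.
    """
    diag = np.diag(kernel.values)
    bad = np.nonzero(diag <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive self-similarity for protein {kernel.proteins[bad[0]]!r}"
        )
    scale = np.sqrt(diag)
    values = kernel.values / np.outer(scale, scale)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(kernel.proteins, values, normalized=True)


def combine_kernels(kernels: Sequence[KernelMatrix]) -> KernelMatrix:
    """Combine data sources by entrywise addition of (normalised) kernels.

    Adding linear kernels over separate feature blocks equals the linear
    kernel over the concatenated features.  All inputs must share the same
    protein ordering.
    """
    if not kernels:
        raise ValueError("no kernels to combine")
    first = kernels[0]
    for k in kernels[1:]:
        if k.proteins != first.proteins:
            raise ValueError("kernels have mismatched protein orderings")
    total = sum((k.values for k in kernels[1:]), first.values.copy())
    return KernelMatrix(first.proteins, total)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_similarity_tsv(path) -> SimilarityTable:
    """Read (query, subject, e-value) triples; duplicates keep the best hit."""
    hits: dict[str, dict[str, float]] = {}
    df = pd.read_csv(
        path, sep="\t", header=None, names=["query", "subject", "evalue"], comment="#"
    )
    for query, subject, evalue in df.itertuples(index=False):
        prev = hits.setdefault(str(query), {}).get(str(subject))
        value = float(evalue)
        if prev is None or value < prev:
            hits[str(query)][str(subject)] = value
    return SimilarityTable(hits)


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read a 2- or 3-column undirected edge list (third column ignored)."""
    edges = []
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            edges.append((fields[0], fields[1]))
    return edges


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {identifier: sequence} (first token of header)."""
    sequences: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                sequences[name] = []
            elif name is None:
                raise ValueError("FASTA sequence data before any header")
            else:
                sequences[name].append(line)
    return {n: "".join(parts) for n, parts in sequences.items()}


def read_feature_table(path) -> pd.DataFrame:
    """Read a generic per-protein feature table (TSV, first column = protein).

    Used for externally computed features: localisation signals,
    transmembrane-domain indicators, literature co-mention counts.  Several
    tables for the same proteins are concatenated column-wise by the caller.
    """
    return pd.read_csv(path, sep="\t", index_col=0)
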