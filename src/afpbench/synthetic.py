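"""Synthetic benchmark corpora with controllable annotation bias.

Generates desk-scale stand-ins for the inputs of a temporal function
prediction benchmark:

* a layered, single-root ontology DAG with occasional diamond motifs;
* time-stamped annotations whose term-sampling distribution drifts
  multiplicatively over the years (category-prevalence drift) and whose
  mean annotation depth rises over time (increasing specificity) — the two
  biases known to separate temporal holdouts from cross-validation;
* a protein network whose edge probability grows with shared annotations
  and, controllably, with a protein's annotation count, reproducing the
  positive degree-multifunctionality coupling of real association networks;
* a pairwise similarity table in which functionally related proteins
  receive small alignment-style e-values.

A designated fraction of proteins receives no pre-cutoff annotation at all:
these become the novel proteins of the NP protocol.  Everything is fully
deterministic under ``SyntheticConfig.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ontology import (
    EXPERIMENTAL_EVIDENCE,
    AnnotationSet,
    OntologyDAG,
    propagate_annotations,
)
from .features import SimilarityTable

__all__ = [
    "SyntheticConfig",
    "generate_dag",
    "generate_annotations",
    "generate_network",
    "generate_similarity",
    "generate_corpus",
    "write_corpus",
]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic corpus generator.

    Defaults describe a drifted corpus of 1000 proteins and 150 terms over
    the years 2000-2014 with the temporal cutoff at 2009 — large enough for
    stable protocol comparisons, small enough to regenerate in seconds.

    Parameters
    ----------
    seed
        RNG seed; equal seeds give byte-identical corpora.
    n_proteins, n_terms
        Corpus size.  ``n_terms`` includes the root.
    dag_depth
        Number of DAG layers including the root (>= 2).
    branching
        Mean children per term; layer sizes grow geometrically with this
        factor until ``n_terms`` is exhausted.
    years
        ``(start, cutoff, end)`` calendar years; the cutoff is the last
        training year and must lie strictly between start and end.
    base_prevalence
        Per-depth multiplicative sampling weight (depth d terms carry
        weight ``base_prevalence ** (d - 1)``); 1.0 = no depth preference.
    drift_rate
        Multiplicative change per year of a term's sampling odds; each term
        drifts up or down (direction drawn at random).  1.0 = no drift.
    specificity_shift
        Per-year increase of the log-odds of deep terms relative to shallow
        ones; positive values make later annotations more specific.
    degree_coupling
        In [0, 1]: strength of the direct link between a protein's
        annotation count and its expected network degree.
    edge_density
        Baseline edge rate of the network (expected edge probability for a
        pair with no shared annotations at zero coupling).
    np_fraction
        Fraction of proteins destined to stay unannotated until after the
        cutoff (the future NP test set), chosen a priori.
    events_per_era
        Mean annotation events per protein in each era (Poisson); the
        pre- and post-cutoff eras use the same mean, so a no-drift corpus
        accrues comparably many annotations on both sides of the cutoff.
    diamond_prob
        Probability that a non-root term receives a second parent.
    n_anchors, affinity
        Functional coherence of proteins: each protein is assigned
        ``n_anchors`` anchor branches of the ontology and its annotation
        events up-weight terms inside those branches by the multiplicative
        factor ``affinity``.  This modularity — a protein's future
        annotations correlate with its past ones — is what gives network
        neighbours and homologs genuine predictive signal.
    """

    seed: int = 0
    n_proteins: int = 1000
    n_terms: int = 150
    dag_depth: int = 5
    branching: float = 3.0
    years: tuple[int, int, int] = (2000, 2009, 2014)
    base_prevalence: float = 1.0
    drift_rate: float = 1.5
    specificity_shift: float = 0.05
    degree_coupling: float = 0.5
    edge_density: float = 0.005
    np_fraction: float = 0.2
    events_per_era: float = 3.0
    diamond_prob: float = 0.15
    n_anchors: int = 2
    affinity: float = 8.0
    namespace: str = "P"

    def __post_init__(self) -> None:
        start, cutoff, end = self.years
        if not (start < cutoff < end):
            raise ValueError("cutoff year must lie strictly inside (start, end)")
        if min(self.n_proteins, self.n_terms) < 2 or self.dag_depth < 2:
            raise ValueError("n_proteins, n_terms and dag_depth must be >= 2")
        if self.drift_rate <= 0 or self.branching <= 0 or self.events_per_era <= 0:
            raise ValueError("drift_rate, branching and events_per_era must be > 0")
        if not 0.0 <= self.degree_coupling <= 1.0:
            raise ValueError("degree_coupling must lie in [0, 1]")
        if not 0.0 <= self.np_fraction < 1.0:
            raise ValueError("np_fraction must lie in [0, 1)")
        if self.edge_density < 0:
            raise ValueError("edge_density must be >= 0")

    @property
    def cutoff_year(self) -> int:
        return self.years[1]

    def protein_names(self) -> list[str]:
        width = len(str(self.n_proteins - 1))
        return [f"P{i:0{width}d}" for i in range(self.n_proteins)]


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------


def generate_dag(config: SyntheticConfig) -> OntologyDAG:
    """Build a layered single-root DAG with ~geometric layer growth.

    Layer sizes below the root are proportional to ``branching ** depth``
    rescaled so the term count is exactly ``n_terms``; each term gets one
    primary parent in the layer above and, with probability
    ``diamond_prob``, a second parent (a diamond motif).
    """
    rng = np.random.default_rng(config.seed)
    n_internal = config.n_terms - 1
    depths = config.dag_depth - 1
    raw = np.array([config.branching**d for d in range(1, depths + 1)])
    sizes = np.maximum(1, np.round(raw / raw.sum() * n_internal)).astype(int)
    # adjust rounding drift so layer sizes sum exactly to n_terms - 1
    while sizes.sum() > n_internal:
        sizes[np.argmax(sizes)] -= 1
    while sizes.sum() < n_internal:
        sizes[np.argmin(sizes)] += 1
    width = len(str(config.n_terms))
    root = f"T{0:0{width}d}"
    namespace = {root: config.namespace}
    edges: list[tuple[str, str]] = []
    layers = [[root]]
    counter = 1
    for size in sizes:
        layer = []
        above = layers[-1]
        for _ in range(size):
            term = f"T{counter:0{width}d}"
            counter += 1
            namespace[term] = config.namespace
            parent = above[rng.integers(len(above))]
            edges.append((term, parent))
            if len(above) > 1 and rng.random() < config.diamond_prob:
                second = above[rng.integers(len(above))]
                if second != parent:
                    edges.append((term, second))
            layer.append(term)
        layers.append(layer)
    return OntologyDAG(edges, namespace)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def _year_weights(config: SyntheticConfig, dag: OntologyDAG, rng) -> pd.DataFrame:
    """Per-year term-sampling distributions (rows: years, columns: terms)."""
    start, _, end = config.years
    terms = sorted(dag.terms - dag.root_terms)
    depths = np.array([dag.depth(t) for t in terms], dtype=float)
    base = rng.lognormal(mean=0.0, sigma=0.5, size=len(terms))
    base *= config.base_prevalence ** (depths - 1)
    direction = rng.choice([-1.0, 1.0], size=len(terms))
    mean_depth = depths.mean()
    years = np.arange(start, end + 1)
    rows = []
    for year in years:
        dt = float(year - start)
        weight = (
            base
            * config.drift_rate ** (direction * dt)
            * np.exp(config.specificity_shift * dt * (depths - mean_depth))
        )
        rows.append(weight / weight.sum())
    return pd.DataFrame(rows, index=years, columns=terms)


def generate_annotations(dag: OntologyDAG, config: SyntheticConfig) -> AnnotationSet:
    """Simulate annotation accrual over the configured year range.

    Every protein receives a Poisson number of annotation events in each
    era (before and after the cutoff).  The event's term is drawn from that
    year's drifted sampling distribution, reweighted by the protein's
    anchor-branch affinity so that a protein's annotations cluster in a few
    ontology branches.  Proteins designated as future novel proteins
    receive no pre-cutoff events and at least one post-cutoff event.  The
    returned set is raw (unpropagated).
    """
    rng = np.random.default_rng(config.seed + 1)
    start, cutoff, end = config.years
    weights = _year_weights(config, dag, rng)
    terms = np.array(weights.columns)
    term_index = {t: j for j, t in enumerate(terms)}
    proteins = config.protein_names()
    n = config.n_proteins
    n_np = int(round(config.np_fraction * n))
    np_proteins = set(rng.choice(n, size=n_np, replace=False).tolist())

    # anchor branches: internal terms two levels below the root when the DAG
    # is deep enough, else the top layer
    depths = {t: dag.depth(t) for t in terms}
    anchor_depth = 2 if any(d == 2 for d in depths.values()) and config.dag_depth > 3 else 1
    candidates = [t for t in terms if depths[t] == anchor_depth]
    membership = np.zeros((len(candidates), len(terms)), dtype=bool)
    for a, anchor in enumerate(candidates):
        membership[a, term_index[anchor]] = True
        for desc in dag.descendants(anchor):
            membership[a, term_index[desc]] = True
    boost = np.ones((n, len(terms)))
    for i in range(n):
        chosen = rng.choice(len(candidates), size=min(config.n_anchors, len(candidates)),
                            replace=False)
        inside = membership[chosen].any(axis=0)
        boost[i, inside] += config.affinity

    event_protein: list[int] = []
    event_year: list[int] = []
    lam = config.events_per_era
    for i in range(n):
        pre = 0 if i in np_proteins else int(rng.poisson(lam))
        post = int(rng.poisson(lam))
        if i in np_proteins and post == 0:
            post = 1
        for _ in range(pre):
            event_protein.append(i)
            event_year.append(int(rng.integers(start, cutoff + 1)))
        for _ in range(post):
            event_protein.append(i)
            event_year.append(int(rng.integers(cutoff + 1, end + 1)))

    event_protein = np.array(event_protein, dtype=int)
    event_year = np.array(event_year, dtype=int)
    year_weights = {y: weights.loc[y].to_numpy() for y in weights.index}
    event_term = np.empty(len(event_protein), dtype=terms.dtype)
    for e in range(len(event_protein)):
        p = year_weights[event_year[e]] * boost[event_protein[e]]
        event_term[e] = rng.choice(terms, p=p / p.sum())
    codes = sorted(EXPERIMENTAL_EVIDENCE)
    event_evidence = rng.choice(codes, size=len(event_protein))

    records = pd.DataFrame(
        {
            "protein": [proteins[i] for i in event_protein],
            "term": event_term,
            "evidence": event_evidence,
            "year": event_year,
        }
    )
    return AnnotationSet(records)


# ---------------------------------------------------------------------------
# Network and similarity
# ---------------------------------------------------------------------------

_SHARED_WEIGHT = 1.0
_DEGREE_WEIGHT = 3.0


def _pair_matrix(
    annotations: AnnotationSet, dag: OntologyDAG | None
) -> tuple[list[str], np.ndarray]:
    if dag is not None and not annotations.propagated:
        annotations = propagate_annotations(annotations, dag)
    proteins = sorted(annotations.proteins)
    terms = sorted(annotations.terms)
    p_index = {p: i for i, p in enumerate(proteins)}
    t_index = {t: j for j, t in enumerate(terms)}
    matrix = np.zeros((len(proteins), len(terms)), dtype=bool)
    for p, t in annotations.pairs():
        matrix[p_index[p], t_index[t]] = True
    return proteins, matrix


def generate_network(
    annotations: AnnotationSet,
    config: SyntheticConfig,
    dag: OntologyDAG | None = None,
) -> list[tuple[str, str]]:
    """Sample an undirected protein network coupled to the annotations.

    The edge rate for a pair grows with the number of pre-cutoff terms the
    two proteins share (functional coherence) and, scaled by
    ``degree_coupling``, with their pre-cutoff annotation counts, so that
    highly annotated (multifunctional) proteins become hubs.  All proteins
    appearing in *annotations* are nodes; passing *dag* counts shared terms
    on the propagated sets.
    """
    rng = np.random.default_rng(config.seed + 2)
    all_proteins = sorted(annotations.proteins)
    pre = annotations.before(config.cutoff_year)
    if len(pre):
        pre_proteins, matrix = _pair_matrix(pre, dag)
    else:
        pre_proteins, matrix = [], np.zeros((0, 0), dtype=bool)
    counts = np.zeros(len(all_proteins))
    shared = np.zeros((len(all_proteins), len(all_proteins)))
    if len(pre_proteins):
        position = {p: i for i, p in enumerate(all_proteins)}
        rows = [position[p] for p in pre_proteins]
        sub_counts = matrix.sum(axis=1).astype(float)
        sub_shared = (matrix.astype(float) @ matrix.T.astype(float))
        counts[rows] = sub_counts
        shared[np.ix_(rows, rows)] = sub_shared
    mean_count = counts.mean() if counts.mean() > 0 else 1.0
    rate = config.edge_density * (
        1.0
        + _SHARED_WEIGHT * shared
        + config.degree_coupling
        * _DEGREE_WEIGHT
        * (counts[:, None] + counts[None, :])
        / (2.0 * mean_count)
    )
    prob = 1.0 - np.exp(-rate)
    n = len(all_proteins)
    draws = rng.random((n, n))
    upper = np.triu(draws < prob, k=1)
    edges = [
        (all_proteins[i], all_proteins[j]) for i, j in zip(*np.nonzero(upper))
    ]
    return edges


def generate_similarity(
    annotations: AnnotationSet,
    config: SyntheticConfig,
    dag: OntologyDAG | None = None,
) -> SimilarityTable:
    """Sample a BLAST-style pairwise e-value table from functional overlap.

    Pairs sharing propagated terms receive hits with probability equal to
    the Jaccard similarity of their term sets; hit e-values are log-uniform
    within [1e-30, 1e-3], tighter for higher overlap, so proteins with
    identical term sets always hit at e <= 1e-10.  Proteins with no term in
    common never hit.
    """
    rng = np.random.default_rng(config.seed + 3)
    proteins, matrix = _pair_matrix(annotations, dag)
    counts = matrix.sum(axis=1).astype(float)
    inter = matrix.astype(float) @ matrix.T.astype(float)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jaccard = np.where(union > 0, inter / union, 0.0)
    hits: dict[str, dict[str, float]] = {}
    n = len(proteins)
    draws = rng.random((n, n))
    exponent_noise = rng.random((n, n)) * 0.6 + 0.4  # uniform in [0.4, 1.0]
    chosen = np.triu((jaccard > 0) & (draws < jaccard), k=1)
    for i, j in zip(*np.nonzero(chosen)):
        exponent = 3.0 + 27.0 * jaccard[i, j] * exponent_noise[i, j]
        evalue = 10.0**-exponent
        hits.setdefault(proteins[i], {})[proteins[j]] = evalue
        hits.setdefault(proteins[j], {})[proteins[i]] = evalue
    return SimilarityTable(hits)


# ---------------------------------------------------------------------------
# Corpus bundle
# ---------------------------------------------------------------------------


def generate_corpus(
    config: SyntheticConfig, with_similarity: bool = False
) -> dict:
    """Generate the full corpus bundle for one configuration.

    Returns a dict with keys ``dag``, ``annotations`` (raw), ``network``
    (edge list) and, when requested, ``similarity``.
    """
    dag = generate_dag(config)
    annotations = generate_annotations(dag, config)
    network = generate_network(annotations, config, dag=dag)
    bundle = {"dag": dag, "annotations": annotations, "network": network}
    if with_similarity:
        bundle["similarity"] = generate_similarity(annotations, config, dag=dag)
    return bundle


def write_corpus(config: SyntheticConfig, out_dir, with_similarity: bool = True) -> dict:
    """Write a corpus to disk (OBO, annotation TSV, edge list, similarity TSV).

    All files round-trip through the package's own readers; a JSON manifest
    records the configuration and basic counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_corpus(config, with_similarity=with_similarity)
    bundle["dag"].to_obo(out / "ontology.obo")
    bundle["annotations"].to_tsv(out / "annotations.tsv", header=False)
    with open(out / "network.tsv", "w") as fh:
        for a, b in bundle["network"]:
            fh.write(f"{a}\t{b}\n")
    if with_similarity:
        with open(out / "similarity.tsv", "w") as fh:
            for query in sorted(bundle["similarity"].hits):
                for subject, evalue in sorted(bundle["similarity"].hits[query].items()):
                    fh.write(f"{query}\t{subject}\t{evalue:.6g}\n")
    manifest = {
        "config": asdict(config),
        "n_terms": len(bundle["dag"]),
        "n_annotation_records": len(bundle["annotations"]),
        "n_proteins": len(bundle["annotations"].proteins),
        "n_edges": len(bundle["network"]),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return bundle
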