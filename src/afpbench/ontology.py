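"""Gene Ontology-style DAG handling: parsing, filtering and true-path propagation.

The Gene Ontology (GO) is a directed acyclic graph of functional categories
("terms") organised into three subontologies (namespaces): molecular function
(F), biological process (P) and cellular component (C).  A protein annotated
to a term is implicitly annotated to every ancestor of that term up to the
namespace root — the *true path rule*.  This module provides

* :class:`OntologyDAG` — the DAG with ancestor/descendant queries,
* :class:`AnnotationSet` — time-stamped (protein, term, evidence, year)
  records with a propagated view,
* :class:`ScoreTable` — protein x term prediction confidences,
* the curation filters applied before benchmarking (evidence codes, root and
  excluded categories, minimum term size),
* upward propagation of annotations (set closure) and of prediction scores
  (parent score = max over descendants), and
* the cross-setup common term universe used for fair comparison.

Term identifiers are opaque strings: real ``GO:NNNNNNN`` identifiers and
synthetic names are treated identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

__all__ = [
    "EXPERIMENTAL_EVIDENCE",
    "PROTEIN_BINDING",
    "OntologyDAG",
    "AnnotationRecord",
    "AnnotationSet",
    "ScoreTable",
    "filter_annotations",
    "propagate_annotations",
    "propagate_scores",
    "common_term_universe",
]

#: Evidence codes regarded as experimental / curator-reviewed.  Annotations
#: inferred computationally (IEA etc.) or from interaction assays (IPI) are
#: excluded from benchmark corpora.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IMP", "IGI", "IEP", "TAS"})

#: The uninformative 'protein binding' molecular-function category, excluded
#: by convention when real GO identifiers are in use.
PROTEIN_BINDING = "GO:0005515"

#: Mapping from OBO namespace names to the one-letter codes used throughout.
NAMESPACE_CODES = {
    "molecular_function": "F",
    "biological_process": "P",
    "cellular_component": "C",
}

#: OBO relationship types traversed as parent edges during propagation.
PARENT_RELATIONS = frozenset({"is_a", "part_of"})


# ---------------------------------------------------------------------------
# DAG
# ---------------------------------------------------------------------------


class OntologyDAG:
    """A rooted, acyclic term hierarchy with one root per namespace.

    Parameters
    ----------
    edges
        Iterable of ``(child, parent)`` pairs.  Both endpoints must share a
        namespace; cross-namespace edges are rejected.
    namespace
        Mapping from every term to its namespace code (any string; GO uses
        ``F``/``P``/``C``).  Terms missing from the mapping are an error.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        namespace: Mapping[str, str],
    ) -> None:
        graph = nx.DiGraph()
        graph.add_nodes_from(namespace)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in namespace:
                    raise KeyError(f"term {endpoint!r} has no namespace entry")
            if namespace[child] != namespace[parent]:
                raise ValueError(
                    f"cross-namespace edge {child!r} -> {parent!r} "
                    f"({namespace[child]} -> {namespace[parent]})"
                )
            graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")

        self._graph = graph
        self.namespace: dict[str, str] = dict(namespace)
        self.roots: dict[str, str] = {}
        for term in graph.nodes:
            if graph.out_degree(term) == 0:
                ns = self.namespace[term]
                if ns in self.roots:
                    raise ValueError(
                        f"namespace {ns!r} has multiple roots: "
                        f"{self.roots[ns]!r} and {term!r}"
                    )
                self.roots[ns] = term
        self._root_set = frozenset(self.roots.values())
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._descendant_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ------------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._graph.nodes)

    @property
    def root_terms(self) -> frozenset[str]:
        return self._root_set

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def is_root(self, term: str) -> bool:
        return term in self._root_set

    def parents(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(self._graph.successors(term))

    def children(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(self._graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All strict ancestors of *term* (including the namespace root)."""
        self._require(term)
        if term not in self._ancestor_cache:
            self._ancestor_cache[term] = frozenset(nx.descendants(self._graph, term))
        return self._ancestor_cache[term]

    def descendants(self, term: str) -> frozenset[str]:
        """All strict descendants of *term*."""
        self._require(term)
        if term not in self._descendant_cache:
            self._descendant_cache[term] = frozenset(nx.ancestors(self._graph, term))
        return self._descendant_cache[term]

    def depth(self, term: str) -> int:
        """Shortest path length from *term* up to its namespace root."""
        self._require(term)
        root = self.roots[self.namespace[term]]
        if term == root:
            return 0
        return nx.shortest_path_length(self._graph, term, root)

    def closure(self, terms: Iterable[str]) -> frozenset[str]:
        """Ancestor closure of a term set, with namespace roots removed.

        Idempotent: ``closure(closure(S)) == closure(S)``.
        """
        out: set[str] = set()
        for term in terms:
            self._require(term)
            if term not in self._root_set:
                out.add(term)
            out.update(self.ancestors(term))
        return frozenset(out - self._root_set)

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents."""
        return list(nx.topological_sort(self._graph))

    def _require(self, term: str) -> None:
        if term not in self._graph:
            raise KeyError(f"unknown ontology term: {term!r}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_obo(cls, path) -> "OntologyDAG":
        """Read an OBO 1.2/1.4 file.

        ``is_a`` and ``relationship: part_of`` edges become parent edges;
        other relationships are ignored, as are obsolete terms.  Namespaces
        named after the three GO subontologies are abbreviated to their
        one-letter codes; any other namespace string is kept verbatim.
        """
        raw = obonet.read_obo(path, ignore_obsolete=True)
        namespace: dict[str, str] = {}
        for term, data in raw.nodes(data=True):
            ns = data.get("namespace", "default")
            namespace[term] = NAMESPACE_CODES.get(ns, ns)
        edges = [
            (child, parent)
            for child, parent, rel in raw.edges(keys=True)
            if rel in PARENT_RELATIONS and parent in namespace
        ]
        return cls(edges, namespace)

    def to_obo(self, path) -> None:
        """Write a minimal OBO 1.2 stanza file (round-trips via from_obo)."""
        inverse_codes = {v: k for k, v in NAMESPACE_CODES.items()}
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.terms):
                ns = self.namespace[term]
                fh.write(f"\n[Term]\nid: {term}\nname: {term}\n")
                fh.write(f"namespace: {inverse_codes.get(ns, ns)}\n")
                for parent in sorted(self.parents(term)):
                    fh.write(f"is_a: {parent}\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


class AnnotationRecord(NamedTuple):
    """A single time-stamped functional annotation."""

    protein: str
    term: str
    evidence: str
    year: int


_COLUMNS = ["protein", "term", "evidence", "year"]


@dataclass
class AnnotationSet:
    """A collection of (protein, term, evidence, year) annotation records.

    ``propagated`` marks sets whose (protein, term) pairs are closed under
    the true path rule (every ancestor pair present, roots excluded).
    """

    records: pd.DataFrame
    propagated: bool = False

    def __post_init__(self) -> None:
        df = self.records
        if list(df.columns) != _COLUMNS:
            df = df.loc[:, _COLUMNS]
        df = df.astype(
            {"protein": str, "term": str, "evidence": str, "year": int}
        ).reset_index(drop=True)
        if (df["evidence"].str.len() == 0).any():
            raise ValueError("evidence codes must be non-empty")
        if (df["year"] <= 0).any():
            raise ValueError("years must be positive integers")
        self.records = df

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, str, int] | AnnotationRecord],
        propagated: bool = False,
    ) -> "AnnotationSet":
        df = pd.DataFrame(list(records), columns=_COLUMNS)
        return cls(df, propagated=propagated)

    @classmethod
    def from_gaf(cls, path) -> "AnnotationSet":
        """Read a GAF 2.x file (columns 2, 5, 7, 14: object id, GO id,
        evidence code, date as YYYYMMDD).  Comment lines start with ``!``."""
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("!"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 14:
                    raise ValueError(f"{path}: line {lineno}: expected >=14 GAF columns")
                date = fields[13]
                rows.append((fields[1], fields[4], fields[6], int(date[:4])))
        return cls.from_records(rows)

    @classmethod
    def from_tsv(cls, path) -> "AnnotationSet":
        """Read the 4-column dialect: protein, term, evidence, year (no header
        required; a ``protein`` header line is skipped)."""
        df = pd.read_csv(path, sep="\t", header=None, names=_COLUMNS, comment="#")
        if len(df) and str(df.iloc[0]["protein"]) == "protein":
            df = df.iloc[1:]
        return cls(df.reset_index(drop=True))

    def to_tsv(self, path, header: bool = True) -> None:
        self.records.to_csv(path, sep="\t", index=False, header=header)

    # -- views --------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.records["protein"])

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.records["term"])

    def pairs(self) -> frozenset[tuple[str, str]]:
        """Distinct (protein, term) pairs."""
        return frozenset(
            zip(self.records["protein"], self.records["term"])
        )

    def protein_to_terms(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for p, t in zip(self.records["protein"], self.records["term"]):
            out.setdefault(p, set()).add(t)
        return {p: frozenset(s) for p, s in out.items()}

    def term_to_proteins(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for p, t in zip(self.records["protein"], self.records["term"]):
            out.setdefault(t, set()).add(p)
        return {t: frozenset(s) for t, s in out.items()}

    def term_counts(self) -> pd.Series:
        """Distinct proteins annotated per term."""
        return self.records.groupby("term")["protein"].nunique()

    def subset(self, mask) -> "AnnotationSet":
        return AnnotationSet(
            self.records.loc[mask].reset_index(drop=True), propagated=self.propagated
        )

    def restrict_proteins(self, proteins: Collection[str]) -> "AnnotationSet":
        return self.subset(self.records["protein"].isin(set(proteins)))

    def restrict_terms(self, terms: Collection[str]) -> "AnnotationSet":
        return self.subset(self.records["term"].isin(set(terms)))

    def before(self, year: int) -> "AnnotationSet":
        """Records with year <= *year* (inclusive cutoff)."""
        return self.subset(self.records["year"] <= year)

    def after(self, year: int) -> "AnnotationSet":
        """Records with year > *year*."""
        return self.subset(self.records["year"] > year)


# ---------------------------------------------------------------------------
# Propagation and filtering
# ---------------------------------------------------------------------------


def propagate_annotations(records: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Apply the true path rule: close every annotation over its ancestors.

    Each record is expanded to one record per ancestor term (namespace roots
    excluded, so direct root annotations vanish); the derived records inherit
    the evidence code and year of the source record.  Duplicate
    (protein, term, evidence, year) rows are collapsed, which makes the
    operation idempotent.
    """
    df = records.records
    unknown = set(df["term"]) - set(dag.terms)
    if unknown:
        raise KeyError(f"unknown ontology term: {sorted(unknown)[0]!r}")
    closure_map = {t: sorted(dag.closure([t])) for t in set(df["term"])}
    counts = df["term"].map(lambda t: len(closure_map[t]))
    expanded = df.loc[df.index.repeat(counts)].copy()
    expanded["term"] = [
        anc for t in df["term"] for anc in closure_map[t]
    ]
    expanded = (
        expanded.drop_duplicates(_COLUMNS)
        .sort_values(_COLUMNS, kind="stable")
        .reset_index(drop=True)
    )
    return AnnotationSet(expanded, propagated=True)


def filter_annotations(
    records: AnnotationSet,
    dag: OntologyDAG,
    allowed_evidence: Collection[str] = EXPERIMENTAL_EVIDENCE,
    excluded_terms: Collection[str] = frozenset(),
    min_proteins: int = 0,
) -> AnnotationSet:
    """Apply the benchmark curation filters and propagate.

    In order: keep records whose evidence code is in *allowed_evidence* and
    whose term is neither a namespace root nor in *excluded_terms*; propagate
    (true path rule); remove excluded terms reintroduced by propagation; and
    finally drop terms annotating fewer than *min_proteins* distinct proteins
    — the size filter is applied once, on the propagated set.

    An empty result is a valid empty set, not an error.
    """
    if min_proteins < 0:
        raise ValueError("min_proteins must be >= 0")
    df = records.records
    unknown = set(df["term"]) - set(dag.terms)
    if unknown:
        raise KeyError(f"unknown ontology term: {sorted(unknown)[0]!r}")
    excluded = set(excluded_terms)
    keep = (
        df["evidence"].isin(set(allowed_evidence))
        & ~df["term"].isin(dag.root_terms)
        & ~df["term"].isin(excluded)
    )
    kept = AnnotationSet(df.loc[keep].reset_index(drop=True))
    propagated = propagate_annotations(kept, dag)
    out = propagated.records
    if excluded:
        out = out.loc[~out["term"].isin(excluded)].reset_index(drop=True)
    if min_proteins > 0:
        counts = out.groupby("term")["protein"].nunique()
        good_terms = set(counts.index[counts >= min_proteins])
        out = out.loc[out["term"].isin(good_terms)].reset_index(drop=True)
    return AnnotationSet(out, propagated=True)


def propagate_scores(scores: "ScoreTable", dag: OntologyDAG) -> "ScoreTable":
    """Propagate prediction confidences toward the root.

    A parent's score becomes the maximum over its descendant set (itself
    included): equivalently, child scores are pushed upward edge by edge in
    topological order.  Roots are dropped from the output.  Idempotent, and
    guarantees score(parent) >= score(child) along every edge.
    """
    values = scores.values
    unknown = set(values.columns) - set(dag.terms)
    if unknown:
        raise KeyError(f"unknown ontology term: {sorted(unknown)[0]!r}")
    if ((values.values < 0) | (values.values > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    relevant = dag.closure(values.columns) | (set(values.columns) - dag.root_terms)
    out = values.reindex(columns=sorted(relevant), fill_value=0.0).astype(float)
    matrix = out.to_numpy()
    column = {term: j for j, term in enumerate(out.columns)}
    for term in dag.topological_order():
        j = column.get(term)
        if j is None:
            continue
        for parent in dag.parents(term):
            jp = column.get(parent)
            if jp is not None:
                np.maximum(matrix[:, jp], matrix[:, j], out=matrix[:, jp])
    return ScoreTable(
        pd.DataFrame(matrix, index=out.index, columns=out.columns), propagated=True
    )


def common_term_universe(splits: Sequence) -> frozenset[str]:
    """Intersection of annotated terms across evaluation setups.

    A term belongs to a setup's inventory if it carries at least one
    propagated annotation in the setup's training or test set.  Downstream
    metrics are restricted to the returned intersection so that every setup
    is scored on the same categories.
    """
    if len(splits) < 2:
        raise ValueError("need at least two splits to intersect")
    universe: frozenset[str] | None = None
    for split in splits:
        inventory = frozenset(split.train.terms) | frozenset(split.test.terms)
        universe = inventory if universe is None else universe & inventory
    assert universe is not None
    if not universe:
        warnings.warn("common term universe is empty", stacklevel=2)
    return universe


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------


@dataclass
class ScoreTable:
    """Protein x term prediction confidences in [0, 1].

    ``values`` is a dense frame indexed by protein with one column per term;
    absent entries are zero by convention.  ``propagated`` marks tables whose
    scores are monotone along child -> parent edges.
    """

    values: pd.DataFrame
    propagated: bool = False

    def __post_init__(self) -> None:
        values = self.values.astype(float)
        if ((values.values < 0) | (values.values > 1)).any():
            raise ValueError("scores must lie in [0, 1]")
        self.values = values

    @classmethod
    def from_long(
        cls, rows: Iterable[tuple[str, str, float]], propagated: bool = False
    ) -> "ScoreTable":
        """Build from (protein, term, score) triples; duplicates keep the max."""
        df = pd.DataFrame(list(rows), columns=["protein", "term", "score"])
        wide = (
            df.pivot_table(index="protein", columns="term", values="score", aggfunc="max")
            .fillna(0.0)
            .rename_axis(index=None, columns=None)
        )
        return cls(wide, propagated=propagated)

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().reset_index()
        long.columns = ["protein", "term", "score"]
        return long.loc[long["score"] > 0].reset_index(drop=True)

    def to_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False, header=False)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def terms(self) -> list[str]:
        return list(self.values.columns)

    def score(self, protein: str, term: str) -> float:
        if protein in self.values.index and term in self.values.columns:
            return float(self.values.at[protein, term])
        return 0.0
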