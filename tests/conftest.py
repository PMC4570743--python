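"""Shared fixtures: tiny hand-built ontologies and random test-case builders."""

from __future__ import annotations

import numpy as np
import pytest

from afpbench import AnnotationSet, OntologyDAG


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """root <- A <- B (B is the most specific term)."""
    return OntologyDAG(
        [("A", "root"), ("B", "A")],
        {"root": "P", "A": "P", "B": "P"},
    )


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """root <- A <- {B, C} <- D (D has two parents)."""
    return OntologyDAG(
        [("A", "root"), ("B", "A"), ("C", "A"), ("D", "B"), ("D", "C")],
        {t: "P" for t in ["root", "A", "B", "C", "D"]},
    )


@pytest.fixture
def wide_dag() -> OntologyDAG:
    """root with two independent branches: A <- {A1, A2}, B <- B1."""
    return OntologyDAG(
        [("A", "root"), ("B", "root"), ("A1", "A"), ("A2", "A"), ("B1", "B")],
        {t: "P" for t in ["root", "A", "B", "A1", "A2", "B1"]},
    )


def random_dag(rng: np.random.Generator, n_terms: int) -> OntologyDAG:
    """A random rooted DAG: node i > 0 picks 1-2 parents among nodes < i.

    Independent of the package's synthetic generator; produces diamonds and
    variable depth.
    """
    names = [f"N{i}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for parent in parents:
            edges.append((names[i], names[parent]))
    return OntologyDAG(edges, {n: "P" for n in names})


def parent_map_of(dag: OntologyDAG) -> dict[str, set[str]]:
    """child -> parents mapping for the brute-force oracles."""
    return {t: set(dag.parents(t)) for t in dag.terms}


def annotations(*records, propagated: bool = False) -> AnnotationSet:
    """Compact builder: annotations(("p1","B"), ("p2","A","IDA",2010))."""
    full = []
    for rec in records:
        protein, term = rec[0], rec[1]
        evidence = rec[2] if len(rec) > 2 else "IDA"
        year = rec[3] if len(rec) > 3 else 2005
        full.append((protein, term, evidence, year))
    return AnnotationSet.from_records(full, propagated=propagated)
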