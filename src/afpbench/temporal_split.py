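"""The three evaluation protocols: cross-validation, novel annotations, novel proteins.

Function-prediction benchmarks that split a corpus at a time point mimic how
annotation databases actually grow.  Writing t1 for the cutoff year, three
annotation sets define the protocols:

* set A — annotations accumulated up to and including t1 (the training set);
* set B — annotations acquired *after* t1 for proteins that already had
  annotations at t1 (the Novel Annotations, NA, test set);
* set C — annotations acquired after t1 for proteins with no annotation at
  t1 (the Novel Proteins, NP, test set).

Cross-validation (CV) ignores time entirely: proteins are shuffled into k
folds and each fold's full annotation sets are predicted from the rest.

Two exclusion rules shape the NA test set: (a) a (protein, term) pair already
present in the propagated training set is not re-tested, even if it was
re-annotated with a new evidence code; (b) a pair whose term has a *more
specific* (strict descendant) training annotation on the same protein is not
tested.  With a propagated training set rule (b) is implied by rule (a) —
the ancestor pair is itself in the closure — but both are applied explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ontology import AnnotationSet, OntologyDAG, propagate_annotations

__all__ = ["EvaluationSplit", "make_cv_folds", "make_na_split", "make_np_split"]


@dataclass
class EvaluationSplit:
    """One evaluation protocol instance.

    ``train`` and ``test`` are propagated annotation sets; for NA the test
    set is additionally post-exclusion (so it is no longer ancestor-closed —
    ancestors already known at training time have been removed).
    ``term_universe`` is the setup's own term inventory (train u test);
    fair cross-protocol comparison intersects these universes downstream.
    """

    protocol: str
    train: AnnotationSet
    test: AnnotationSet
    cutoff_year: int | None = None
    term_universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.term_universe:
            self.term_universe = frozenset(self.train.terms) | frozenset(self.test.terms)

    @property
    def train_proteins(self) -> frozenset[str]:
        return self.train.proteins

    @property
    def test_proteins(self) -> frozenset[str]:
        return self.test.proteins


def make_cv_folds(
    records: AnnotationSet, k: int = 5, seed: int = 42
) -> list[EvaluationSplit]:
    """Split proteins into *k* cross-validation folds.

    Folds partition the protein set: proteins are shuffled with *seed* and
    cut into k near-equal groups (sizes differ by at most one, larger groups
    first).  Fold i trains on all annotations of proteins outside group i
    and tests on the annotations of group i.  *records* must already be
    propagated; the same seed always yields the same folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not records.propagated:
        raise ValueError("CV folds require a propagated annotation set")
    proteins = sorted(records.proteins)
    if len(proteins) < k:
        raise ValueError(f"cannot make {k} folds from {len(proteins)} proteins")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    shuffled = [proteins[i] for i in order]
    groups = np.array_split(np.arange(len(proteins)), k)
    splits = []
    for i, group in enumerate(groups):
        test_proteins = {shuffled[j] for j in group}
        test = records.restrict_proteins(test_proteins)
        train = records.subset(~records.records["protein"].isin(test_proteins))
        splits.append(
            EvaluationSplit(protocol=f"CV-fold-{i}", train=train, test=test)
        )
    return splits


def _training_era(
    records: AnnotationSet, dag: OntologyDAG, cutoff_year: int
) -> tuple[AnnotationSet, frozenset[str]]:
    pre = records.before(cutoff_year)
    train = propagate_annotations(pre, dag)
    return train, train.proteins


def make_na_split(
    records: AnnotationSet, dag: OntologyDAG, cutoff_year: int
) -> EvaluationSplit:
    """Build the Novel Annotations protocol (set A trains, set B tests).

    Training: propagated annotations with year <= *cutoff_year*, restricted
    to proteins having at least one such annotation.  Test candidates: the
    propagated post-cutoff annotations of those same proteins, minus pairs
    excluded by rules (a) and (b) documented in the module docstring.
    """
    train, train_proteins = _training_era(records, dag, cutoff_year)
    post = records.after(cutoff_year).restrict_proteins(train_proteins)
    if len(post) == 0:
        warnings.warn("no post-cutoff annotations for training proteins; NA test empty")
        test = AnnotationSet.from_records([], propagated=True)
        return EvaluationSplit("NA", train, test, cutoff_year)
    candidates = propagate_annotations(post, dag)
    train_pairs = train.pairs()
    train_terms_by_protein = train.protein_to_terms()

    def excluded(protein: str, term: str) -> bool:
        # rule (a): pair already known at training time
        if (protein, term) in train_pairs:
            return True
        # rule (b): a strictly more specific training annotation exists
        known = train_terms_by_protein.get(protein, frozenset())
        return bool(known & dag.descendants(term))

    df = candidates.records
    keep = [
        not excluded(p, t) for p, t in zip(df["protein"], df["term"])
    ]
    test = AnnotationSet(df.loc[keep].reset_index(drop=True), propagated=True)
    return EvaluationSplit("NA", train, test, cutoff_year)


def make_np_split(
    records: AnnotationSet, dag: OntologyDAG, cutoff_year: int
) -> EvaluationSplit:
    """Build the Novel Proteins protocol (set A trains, set C tests).

    Training is identical to NA.  The test set is the propagated post-cutoff
    annotations of proteins with *zero* annotations at or before the cutoff,
    so training and test protein sets are disjoint by construction.
    """
    train, train_proteins = _training_era(records, dag, cutoff_year)
    post = records.after(cutoff_year)
    novel = post.subset(~post.records["protein"].isin(train_proteins))
    if len(novel) == 0:
        warnings.warn("no annotations for novel proteins after the cutoff; NP test empty")
        test = AnnotationSet.from_records([], propagated=True)
    else:
        test = propagate_annotations(novel, dag)
    return EvaluationSplit("NP", train, test, cutoff_year)
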