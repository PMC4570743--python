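"""Protein-centric and term-centric evaluation metrics.

All metrics operate on *propagated* score tables and ground truth (parent
confidence >= child confidence; annotation sets closed under the true path
rule) and sweep a threshold t over (0, 1]: at threshold t, a (protein, term)
pair is predicted when its score is >= t.

Protein-centric F-max averages per-protein precision and recall over all N
test proteins at each threshold,

    P_pc(t) = (1/N) sum_i TP_i / (TP_i + FP_i)
    R_pc(t) = (1/N) sum_i TP_i / (TP_i + FN_i)

and maximises the harmonic mean 2 P R / (P + R) over t.  A protein with no
predictions at t contributes 0 to the precision average — the average runs
over all N proteins with no coverage correction, which differs from the
CAFA assessment convention of averaging precision over covered proteins
only.  Term-centric F-max computes per-term precision/recall over proteins,
takes the per-term maximum over t, and reports the arithmetic mean over
terms with at least one positive test protein.  Per-term AUC is the
rank-based ROC area (ties count one half).

For the Novel Annotations protocol, annotations already known at training
time are *masked*: removed from the test ground truth and excluded from the
negative set of the affected (protein, term) pairs, so a method is neither
rewarded nor penalised for re-predicting what was already known.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import (
    AnnotationSet,
    OntologyDAG,
    ScoreTable,
    propagate_annotations,
    propagate_scores,
)

__all__ = [
    "default_thresholds",
    "observed_thresholds",
    "FmaxResult",
    "TermFmaxResult",
    "MetricsReport",
    "protein_centric_fmax",
    "term_centric_fmax",
    "term_auc",
    "restrict_to_min_annotations",
    "evaluate_split",
    "training_mask",
]


def default_thresholds(step: float = 0.01) -> np.ndarray:
    """The default threshold grid t in {step, 2*step, ..., 1.0}."""
    n = int(round(1.0 / step))
    return np.round(np.arange(1, n + 1) * step, 10)


def observed_thresholds(scores: np.ndarray) -> np.ndarray:
    """Exhaustive sweep: every distinct positive score value, ascending."""
    values = np.unique(scores)
    return values[values > 0]


@dataclass
class FmaxResult:
    """Outcome of a protein-centric F-max sweep."""

    fmax: float
    threshold: float
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_proteins: int

    @property
    def curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "precision": self.precision,
                "recall": self.recall,
            }
        )


@dataclass
class TermFmaxResult:
    """Outcome of a term-centric F-max sweep."""

    fmax_tc: float
    per_term: pd.Series
    excluded_terms: list[str]
    n_proteins: int


@dataclass
class MetricsReport:
    """All metrics for one (score table, evaluation split) pairing."""

    protocol: str
    fmax_pc: float
    fmax_pc_threshold: float
    fmax_tc: float
    per_term_fmax: pd.Series
    per_term_auc: pd.Series
    n_proteins: int
    n_terms: int
    excluded_terms: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "fmax_pc": self.fmax_pc,
            "fmax_pc_threshold": self.fmax_pc_threshold,
            "fmax_tc": self.fmax_tc,
            "n_proteins": self.n_proteins,
            "n_terms": self.n_terms,
            "n_excluded_terms": len(self.excluded_terms),
        }


# ---------------------------------------------------------------------------
# Matrix assembly
# ---------------------------------------------------------------------------


def _assemble(
    scores: ScoreTable,
    truth: AnnotationSet,
    universe: Collection[str] | None,
    mask: Collection[tuple[str, str]] | None,
    dag: OntologyDAG | None,
):
    """Align scores, truth and mask on (test protein x term) matrices.

    Test proteins are the proteins of the ground truth; terms default to the
    union of truth and score terms when no universe is given.  Returns
    (proteins, terms, S, Y, M) with S float scores, Y boolean truth and M
    boolean mask (masked cells take part in neither predictions nor truth).
    """
    if dag is not None:
        scores = propagate_scores(scores, dag)
        truth = propagate_annotations(truth, dag)
    elif not truth.propagated:
        raise ValueError("ground truth must be propagated (or pass dag=...)")
    if len(truth) == 0:
        raise ValueError("ground truth is empty")
    if universe is None:
        terms = sorted(set(truth.terms) | set(scores.terms))
    else:
        terms = sorted(universe)
    proteins = sorted(truth.proteins)
    s = (
        scores.values.reindex(index=proteins, columns=terms)
        .fillna(0.0)
        .to_numpy(dtype=float)
    )
    y = np.zeros((len(proteins), len(terms)), dtype=bool)
    p_index = {p: i for i, p in enumerate(proteins)}
    t_index = {t: j for j, t in enumerate(terms)}
    for protein, term in truth.pairs():
        j = t_index.get(term)
        if j is not None:
            y[p_index[protein], j] = True
    m = np.zeros_like(y)
    if mask:
        for protein, term in mask:
            i, j = p_index.get(protein), t_index.get(term)
            if i is not None and j is not None:
                m[i, j] = True
    y &= ~m
    keep = y.any(axis=1)
    if not keep.all():
        proteins = [p for p, k in zip(proteins, keep) if k]
        s, y, m = s[keep], y[keep], m[keep]
    if not len(proteins):
        raise ValueError("no test proteins with ground-truth annotations remain")
    return proteins, terms, s, y, m


def _resolve_thresholds(thresholds, s: np.ndarray) -> np.ndarray:
    if thresholds is None:
        return default_thresholds()
    if isinstance(thresholds, str):
        if thresholds == "observed":
            return observed_thresholds(s)
        raise ValueError(f"unknown threshold mode {thresholds!r}")
    return np.asarray(thresholds, dtype=float)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def protein_centric_fmax(
    scores: ScoreTable,
    truth: AnnotationSet,
    thresholds=None,
    universe: Collection[str] | None = None,
    mask: Collection[tuple[str, str]] | None = None,
    dag: OntologyDAG | None = None,
) -> FmaxResult:
    """Protein-centric F-max over a threshold sweep.

    *thresholds* may be an explicit array, ``None`` for the default 0.01
    grid, or ``"observed"`` for the exhaustive sweep over distinct score
    values.  Passing *dag* re-propagates scores and truth defensively
    (idempotent).  *mask* removes (protein, term) cells from both
    predictions and truth.
    """
    proteins, terms, s, y, m = _assemble(scores, truth, universe, mask, dag)
    ts = _resolve_thresholds(thresholds, s)
    return _pc_sweep(proteins, s, y, m, ts)


def _pc_sweep(proteins, s, y, m, ts) -> FmaxResult:
    if ts.size == 0:
        return FmaxResult(0.0, 0.0, ts, np.array([]), np.array([]), len(proteins))
    n = len(proteins)
    n_true = y.sum(axis=1).astype(float)
    precision = np.empty(ts.size)
    recall = np.empty(ts.size)
    usable = ~m
    for idx, t in enumerate(ts):
        predicted = (s >= t) & usable
        tp = (predicted & y).sum(axis=1).astype(float)
        n_pred = predicted.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_protein_precision = np.where(n_pred > 0, tp / n_pred, 0.0)
        precision[idx] = per_protein_precision.mean()
        recall[idx] = (tp / n_true).mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )
    best = int(np.argmax(f))
    return FmaxResult(float(f[best]), float(ts[best]), ts, precision, recall, n)


def term_centric_fmax(
    scores: ScoreTable,
    truth: AnnotationSet,
    thresholds=None,
    universe: Collection[str] | None = None,
    mask: Collection[tuple[str, str]] | None = None,
    dag: OntologyDAG | None = None,
) -> TermFmaxResult:
    """Per-term F-max values and their mean.

    For each term j, precision and recall are computed over test proteins
    at every threshold and the harmonic mean is maximised; thresholds with
    no predicted protein yield F = 0 for that term.  Terms with no positive
    test protein are excluded from the mean and reported.
    """
    proteins, terms, s, y, m = _assemble(scores, truth, universe, mask, dag)
    ts = _resolve_thresholds(thresholds, s)
    return _tc_sweep(proteins, terms, s, y, m, ts)


def _tc_sweep(proteins, terms, s, y, m, ts) -> TermFmaxResult:
    n_pos = y.sum(axis=0).astype(float)
    evaluable = n_pos > 0
    excluded = [t for t, ok in zip(terms, evaluable) if not ok]
    per_term = np.zeros(len(terms))
    usable = ~m
    if ts.size:
        for idx, t in enumerate(ts):
            predicted = (s >= t) & usable
            tp = (predicted & y).sum(axis=0).astype(float)
            n_pred = predicted.sum(axis=0).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                p_j = np.where(n_pred > 0, tp / n_pred, 0.0)
                r_j = np.where(n_pos > 0, tp / n_pos, 0.0)
                f_j = np.where(p_j + r_j > 0, 2 * p_j * r_j / (p_j + r_j), 0.0)
            per_term = np.maximum(per_term, f_j)
    series = pd.Series(per_term, index=terms)[evaluable]
    mean = float(series.mean()) if len(series) else 0.0
    return TermFmaxResult(mean, series, excluded, len(proteins))


def term_auc(
    scores: ScoreTable,
    truth: AnnotationSet,
    universe: Collection[str] | None = None,
    mask: Collection[tuple[str, str]] | None = None,
    dag: OntologyDAG | None = None,
) -> pd.Series:
    """Rank-based ROC AUC per term (ties contribute one half).

    A term needs at least one positive and one negative test protein after
    masking; degenerate terms are skipped (absent from the result).
    """
    proteins, terms, s, y, m = _assemble(scores, truth, universe, mask, dag)
    return _auc_columns(terms, s, y, m)


def _auc_columns(terms, s, y, m) -> pd.Series:
    out = {}
    for j, term in enumerate(terms):
        usable = ~m[:, j]
        labels = y[usable, j]
        n_pos = int(labels.sum())
        if n_pos == 0 or n_pos == labels.size:
            continue
        # Mann-Whitney form of the ROC area: ties contribute one half.
        ranks = stats.rankdata(s[usable, j])
        n_neg = labels.size - n_pos
        u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
        out[term] = float(u / (n_pos * n_neg))
    return pd.Series(out, dtype=float)


def restrict_to_min_annotations(truth: AnnotationSet, min_count: int) -> frozenset[str]:
    """Terms annotating at least *min_count* distinct test proteins.

    Used for the well-represented-category sub-evaluation (e.g. terms with
    50 or more annotations).
    """
    if not truth.propagated:
        raise ValueError("truth must be propagated")
    counts = truth.term_counts()
    return frozenset(counts.index[counts >= min_count])


# ---------------------------------------------------------------------------
# Split-level convenience
# ---------------------------------------------------------------------------


def training_mask(split) -> frozenset[tuple[str, str]]:
    """Training-era (protein, term) pairs of the split's test proteins.

    For the Novel Annotations protocol these are the annotations already
    known before the cutoff; they are masked during evaluation rather than
    counted as negatives.
    """
    test_proteins = split.test.proteins
    return frozenset(
        (p, t) for (p, t) in split.train.pairs() if p in test_proteins
    )


def evaluate_split(
    scores: ScoreTable,
    split,
    universe: Collection[str] | None = None,
    thresholds=None,
    dag: OntologyDAG | None = None,
    mask_training: bool = True,
) -> MetricsReport:
    """Compute the full metric report for one protocol instance.

    For NA splits, training-era annotations of the test proteins are masked
    by default (``mask_training=True``); set it to False for removal-only
    semantics, where those pairs count as ordinary negatives.  Other
    protocols evaluate unmasked.
    """
    mask: frozenset[tuple[str, str]] = frozenset()
    if mask_training and split.protocol == "NA":
        mask = training_mask(split)
    universe = split.term_universe if universe is None else universe
    proteins, terms, s, y, m = _assemble(scores, split.test, universe, mask, dag)
    ts = _resolve_thresholds(thresholds, s)
    pc = _pc_sweep(proteins, s, y, m, ts)
    tc = _tc_sweep(proteins, terms, s, y, m, ts)
    auc = _auc_columns(terms, s, y, m)
    return MetricsReport(
        protocol=split.protocol,
        fmax_pc=pc.fmax,
        fmax_pc_threshold=pc.threshold,
        fmax_tc=tc.fmax_tc,
        per_term_fmax=tc.per_term,
        per_term_auc=auc,
        n_proteins=pc.n_proteins,
        n_terms=len(tc.per_term),
        excluded_terms=tc.excluded_terms,
    )
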