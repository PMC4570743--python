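"""Train/test label-distribution drift diagnostics.

The prevalence of term i in an annotation set is the fraction of the set's
proteins annotated with it, p_i = (annotated proteins) / (total proteins).
With training prevalence p_tr and test prevalence p_tst, the *discrepancy*
of a term is

    |p_tr - p_tst| / (p_tr + p_tst),

a normalised measure in [0, 1] of how differently the term is represented
across the temporal split; the *signed* variant (p_tr - p_tst)/(p_tr + p_tst)
keeps the direction of the drift.  Terms absent from both sets are excluded
(the ratio is undefined), not assigned zero.

The module also provides the correlation and paired-comparison statistics
used to relate drift to performance: Pearson correlation between per-term
metric values (e.g. AUC) and per-term covariates (e.g. discrepancy), and
paired t-tests between two protocols' per-term metric vectors.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import AnnotationSet

__all__ = [
    "DiscrepancyResult",
    "discrepancy",
    "cv_discrepancy",
    "correlate",
    "paired_compare",
    "PairedComparison",
]


class DiscrepancyResult:
    """Per-term prevalence drift table plus its mean.

    ``table`` has columns ``p_tr``, ``p_tst``, ``signed`` and ``absolute``,
    indexed by term; ``mean`` is the mean absolute discrepancy over included
    terms and ``n_excluded`` counts universe terms absent from both sets.
    """

    def __init__(self, table: pd.DataFrame, n_excluded: int) -> None:
        self.table = table
        self.n_excluded = n_excluded

    @property
    def mean(self) -> float:
        return float(self.table["absolute"].mean()) if len(self.table) else float("nan")

    def __repr__(self) -> str:
        return (
            f"DiscrepancyResult(n_terms={len(self.table)}, "
            f"mean={self.mean:.4f}, n_excluded={self.n_excluded})"
        )


def _prevalence(annotations: AnnotationSet, universe: Sequence[str]) -> pd.Series:
    n = len(annotations.proteins)
    counts = annotations.term_counts().reindex(universe, fill_value=0)
    if n == 0:
        return counts.astype(float) * 0.0
    return counts / n


def discrepancy(
    train: AnnotationSet,
    test: AnnotationSet,
    universe,
) -> DiscrepancyResult:
    """Per-term prevalence discrepancy between a training and a test set.

    Prevalences are computed over each set's own protein count.  Terms of
    the universe absent from both sets are excluded and counted.
    """
    universe = sorted(universe)
    if not universe:
        raise ValueError("term universe is empty")
    if not (train.propagated and test.propagated):
        raise ValueError("discrepancy requires propagated annotation sets")
    p_tr = _prevalence(train, universe)
    p_tst = _prevalence(test, universe)
    total = p_tr + p_tst
    included = total > 0
    signed = (p_tr[included] - p_tst[included]) / total[included]
    table = pd.DataFrame(
        {
            "p_tr": p_tr[included],
            "p_tst": p_tst[included],
            "signed": signed,
            "absolute": signed.abs(),
        }
    )
    return DiscrepancyResult(table, int((~included).sum()))


def cv_discrepancy(folds: Sequence, universe) -> DiscrepancyResult:
    """Cross-validation discrepancy: per-fold tables averaged across folds.

    Each fold contributes its own per-term discrepancy (train vs test
    prevalence within the fold); per-term values are then averaged over the
    folds in which the term was defined.
    """
    if not folds:
        raise ValueError("no folds given")
    tables = [discrepancy(f.train, f.test, universe).table for f in folds]
    combined = pd.concat(tables, keys=range(len(tables)))
    averaged = combined.groupby(level=1).mean()
    n_excluded = len(set(universe) - set(averaged.index))
    return DiscrepancyResult(averaged, n_excluded)


def correlate(
    metric_per_term: Mapping[str, float] | pd.Series,
    covariate_per_term: Mapping[str, float] | pd.Series,
    method: str = "pearson",
) -> tuple[float, float, int]:
    """Correlation between two per-term quantities over their shared terms.

    Returns ``(coefficient, p_value, n_terms_used)``.  Pearson is the
    primary method; Spearman is available for robustness checks.  Fewer
    than three shared terms is an error.
    """
    a = pd.Series(metric_per_term, dtype=float)
    b = pd.Series(covariate_per_term, dtype=float)
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared terms; need at least 3")
    x, y = a[shared].to_numpy(), b[shared].to_numpy()
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p), len(shared)


class PairedComparison:
    """Result of a paired t-test between two per-term metric vectors."""

    def __init__(self, mean_difference, t_statistic, p_value, n_terms, n_unpaired):
        self.mean_difference = mean_difference
        self.t_statistic = t_statistic
        self.p_value = p_value
        self.n_terms = n_terms
        self.n_unpaired = n_unpaired

    def __repr__(self) -> str:
        return (
            f"PairedComparison(mean_difference={self.mean_difference:.4f}, "
            f"p_value={self.p_value:.3g}, n_terms={self.n_terms})"
        )


def paired_compare(
    values_a: Mapping[str, float] | pd.Series,
    values_b: Mapping[str, float] | pd.Series,
) -> PairedComparison:
    """Paired t-test between two protocols' per-term metrics.

    Pairs by term; terms present in only one input are excluded and counted.
    ``mean_difference`` is mean(a - b).  When the paired differences have
    zero variance the t statistic is undefined: the exact-tie case reports
    p = 1 for a zero mean difference and p = 0 for a non-zero constant
    difference, with a warning.
    """
    a = pd.Series(values_a, dtype=float)
    b = pd.Series(values_b, dtype=float)
    shared = sorted(set(a.index) & set(b.index))
    n_unpaired = len(set(a.index) ^ set(b.index))
    if len(shared) < 2:
        raise ValueError(f"only {len(shared)} shared terms; need at least 2")
    diff = a[shared].to_numpy() - b[shared].to_numpy()
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        warnings.warn("paired differences have zero variance; exact-tie p-value")
        p = 1.0 if np.isclose(mean_diff, 0.0) else 0.0
        t = 0.0 if np.isclose(mean_diff, 0.0) else float("inf") * np.sign(mean_diff)
        return PairedComparison(mean_diff, t, p, len(shared), n_unpaired)
    t, p = stats.ttest_rel(a[shared].to_numpy(), b[shared].to_numpy())
    return PairedComparison(mean_diff, float(t), float(p), len(shared), n_unpaired)
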