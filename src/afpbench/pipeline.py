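"""End-to-end benchmark driver: corpus -> splits -> predictions -> metrics.

Ties the pieces together for a full protocol comparison on one corpus:
build the CV folds and the NA/NP temporal splits, run the built-in
predictors on a shared network/kernel, evaluate everything on the common
term universe, and compute the drift diagnostics.  This is what the
command-line ``benchmark`` command and the reproduction script drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .discrepancy import DiscrepancyResult, correlate, cv_discrepancy, discrepancy
from .evaluation import MetricsReport, evaluate_split
from .features import KernelMatrix, linear_kernel, network_adjacency_features, normalize_kernel
from .ontology import (
    AnnotationSet,
    OntologyDAG,
    common_term_universe,
    propagate_annotations,
)
from .predictors import gba_predict, kernel_knn_score, node_degree_predict
from .synthetic import SyntheticConfig, generate_corpus
from .temporal_split import EvaluationSplit, make_cv_folds, make_na_split, make_np_split

__all__ = ["BenchmarkResult", "run_benchmark", "build_splits"]

BUILTIN_PREDICTORS = ("gba", "knn", "degree")

#: Minimum number of positive test proteins a term needs for its AUC to
#: enter the AUC-vs-discrepancy correlation; rank areas estimated from a
#: handful of positives are dominated by noise.
MIN_AUC_SUPPORT = 10


@dataclass
class BenchmarkResult:
    """All quantities produced by one benchmark run.

    ``fmax_pc[predictor][protocol]`` / ``fmax_tc[...]`` hold protein- and
    term-centric F-max per predictor and protocol (CV values are means over
    folds); ``reports`` keeps the full per-split metric reports;
    ``mean_discrepancy[protocol]`` the average per-term prevalence drift;
    ``auc_discrepancy_r[predictor]`` the Pearson correlation between
    per-term AUC and per-term discrepancy in the NA protocol.
    """

    fmax_pc: dict[str, dict[str, float]]
    fmax_tc: dict[str, dict[str, float]]
    mean_discrepancy: dict[str, float]
    auc_discrepancy_r: dict[str, float]
    reports: dict[str, dict[str, list[MetricsReport]]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()
    n_proteins: int = 0


def build_splits(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    cutoff_year: int,
    k: int = 5,
    cv_seed: int = 42,
) -> dict[str, list[EvaluationSplit]]:
    """CV folds plus the NA and NP temporal splits of one corpus."""
    propagated = propagate_annotations(annotations, dag)
    return {
        "CV": make_cv_folds(propagated, k=k, seed=cv_seed),
        "NA": [make_na_split(annotations, dag, cutoff_year)],
        "NP": [make_np_split(annotations, dag, cutoff_year)],
    }


def _predict(method: str, split: EvaluationSplit, adjacency, kernel, universe, knn_k):
    test_proteins = sorted(split.test.proteins)
    if method == "gba":
        return gba_predict(adjacency, split.train, test_proteins, universe)
    if method == "degree":
        return node_degree_predict(adjacency, test_proteins, universe)
    if method == "knn":
        return kernel_knn_score(kernel, split.train, test_proteins, universe, k=knn_k)
    raise ValueError(f"unknown predictor {method!r}")


def run_benchmark(
    config: SyntheticConfig,
    predictors=BUILTIN_PREDICTORS,
    k_folds: int = 5,
    knn_k: int = 10,
    keep_reports: bool = False,
) -> BenchmarkResult:
    """Run the full three-protocol comparison on one synthetic corpus.

    The network is generated once from the corpus and shared by every
    protocol, mirroring a fixed feature set; its normalised linear kernel
    over adjacency vectors drives the kNN predictor.  Metrics are computed
    on the common term universe of the three setups.
    """
    bundle = generate_corpus(config)
    dag: OntologyDAG = bundle["dag"]
    annotations: AnnotationSet = bundle["annotations"]
    splits = build_splits(
        dag, annotations, config.cutoff_year, k=k_folds, cv_seed=config.seed + 100
    )
    all_splits = [s for group in splits.values() for s in group]
    universe = common_term_universe(all_splits)

    proteins = sorted(annotations.proteins)
    adjacency = network_adjacency_features(bundle["network"], proteins)
    kernel = _safe_kernel(adjacency)

    fmax_pc: dict[str, dict[str, float]] = {m: {} for m in predictors}
    fmax_tc: dict[str, dict[str, float]] = {m: {} for m in predictors}
    auc_r: dict[str, float] = {}
    reports: dict[str, dict[str, list[MetricsReport]]] = {m: {} for m in predictors}

    na_split = splits["NA"][0]
    na_disc = discrepancy(na_split.train, na_split.test, universe)

    for method in predictors:
        for protocol, group in splits.items():
            group_reports = []
            for split in group:
                scores = _predict(method, split, adjacency, kernel, universe, knn_k)
                group_reports.append(
                    evaluate_split(scores, split, universe=universe, dag=dag)
                )
            fmax_pc[method][protocol] = float(
                sum(r.fmax_pc for r in group_reports) / len(group_reports)
            )
            fmax_tc[method][protocol] = float(
                sum(r.fmax_tc for r in group_reports) / len(group_reports)
            )
            if keep_reports:
                reports[method][protocol] = group_reports
            if protocol == "NA":
                auc = group_reports[0].per_term_auc
                support = na_split.test.term_counts()
                well_supported = auc[
                    support.reindex(auc.index).fillna(0) >= MIN_AUC_SUPPORT
                ]
                try:
                    r, _, _ = correlate(well_supported, na_disc.table["absolute"])
                except ValueError:
                    r = float("nan")
                auc_r[method] = r

    mean_disc = {
        "CV": cv_discrepancy(splits["CV"], universe).mean,
        "NA": na_disc.mean,
        "NP": discrepancy(splits["NP"][0].train, splits["NP"][0].test, universe).mean,
    }
    return BenchmarkResult(
        fmax_pc=fmax_pc,
        fmax_tc=fmax_tc,
        mean_discrepancy=mean_disc,
        auc_discrepancy_r=auc_r,
        reports=reports if keep_reports else {},
        universe=universe,
        n_proteins=len(proteins),
    )


def _safe_kernel(adjacency: pd.DataFrame) -> KernelMatrix:
    """Linear kernel over adjacency vectors with isolated nodes made valid.

    An isolated protein has an all-zero feature vector and a zero kernel
    diagonal, which cosine normalisation rejects; a unit self-similarity is
    substituted so such proteins are simply dissimilar from everything.
    """
    raw = linear_kernel(adjacency)
    values = raw.values.copy()
    diag = values.diagonal().copy()
    zero = diag == 0
    if zero.any():
        idx = zero.nonzero()[0]
        values[idx, idx] = 1.0
    return normalize_kernel(KernelMatrix(raw.proteins, values))
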