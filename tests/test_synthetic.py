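"""Synthetic corpus generator: determinism, structure, bias contracts."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from afpbench import (
    SyntheticConfig,
    cv_discrepancy,
    common_term_universe,
    discrepancy,
    emax_features,
    generate_annotations,
    generate_corpus,
    generate_dag,
    generate_network,
    generate_similarity,
    propagate_annotations,
    write_corpus,
)
from afpbench.ontology import AnnotationSet, OntologyDAG
from afpbench.features import read_edge_list, read_similarity_tsv
from afpbench.pipeline import build_splits
from conftest import annotations


SMALL = dict(n_proteins=120, n_terms=40, dag_depth=4)


def test_config_validation():
    with pytest.raises(ValueError, match="cutoff"):
        SyntheticConfig(years=(2000, 2014, 2009))
    with pytest.raises(ValueError, match="degree_coupling"):
        SyntheticConfig(degree_coupling=1.5)
    with pytest.raises(ValueError, match="drift_rate"):
        SyntheticConfig(drift_rate=0.0)


# -- DAG --------------------------------------------------------------------


def test_dag_depth_two_branching_three():
    dag = generate_dag(SyntheticConfig(seed=0, n_terms=4, dag_depth=2, branching=3))
    root = dag.roots["P"]
    leaves = dag.terms - {root}
    assert len(leaves) == 3
    assert all(dag.parents(leaf) == {root} for leaf in leaves)


def test_dag_structure_and_reachability():
    dag = generate_dag(SyntheticConfig(seed=3, **SMALL))
    assert len(dag) == SMALL["n_terms"]
    root = dag.roots["P"]
    for term in dag.terms - {root}:
        assert root in dag.ancestors(term)  # all terms reachable from root
        assert dag.depth(term) <= SMALL["dag_depth"] - 1


def test_dag_deterministic_under_seed():
    cfg = SyntheticConfig(seed=11, **SMALL)
    a, b = generate_dag(cfg), generate_dag(cfg)
    assert a.terms == b.terms
    assert {(c, p) for c in a.terms for p in a.parents(c)} == {
        (c, p) for c in b.terms for p in b.parents(c)
    }


# -- annotations ------------------------------------------------------------


def test_annotations_deterministic_under_seed():
    cfg = SyntheticConfig(seed=5, **SMALL)
    dag = generate_dag(cfg)
    a = generate_annotations(dag, cfg)
    b = generate_annotations(dag, cfg)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_np_fraction_reserved_until_after_cutoff():
    cfg = SyntheticConfig(seed=7, np_fraction=0.25, **SMALL)
    dag = generate_dag(cfg)
    records = generate_annotations(dag, cfg)
    pre = records.before(cfg.cutoff_year)
    post = records.after(cfg.cutoff_year)
    novel = post.proteins - pre.proteins
    # at least the designated fraction of annotated proteins is novel
    assert len(novel) >= 0.2 * len(records.proteins)


def test_specificity_shift_deepens_late_annotations():
    cfg = SyntheticConfig(seed=9, specificity_shift=0.1, drift_rate=1.0, **SMALL)
    dag = generate_dag(cfg)
    records = generate_annotations(dag, cfg)
    depth = records.records["term"].map(dag.depth)
    pre = depth[records.records["year"] <= cfg.cutoff_year]
    post = depth[records.records["year"] > cfg.cutoff_year]
    assert post.mean() > pre.mean()


def test_evidence_codes_are_experimental():
    cfg = SyntheticConfig(seed=13, **SMALL)
    records = generate_annotations(generate_dag(cfg), cfg)
    from afpbench import EXPERIMENTAL_EVIDENCE
    assert set(records.records["evidence"]) <= EXPERIMENTAL_EVIDENCE


def test_no_drift_corpus_has_low_na_discrepancy():
    # with drift off, pre- and post-cutoff sampling distributions coincide
    hits = 0
    for seed in range(3):
        cfg = SyntheticConfig(seed=seed, drift_rate=1.0, specificity_shift=0.0,
                              n_proteins=700)
        bundle = generate_corpus(cfg)
        splits = build_splits(bundle["dag"], bundle["annotations"], cfg.cutoff_year)
        na = splits["NA"][0]
        universe = common_term_universe(
            [s for group in splits.values() for s in group]
        )
        drifted_cfg = SyntheticConfig(seed=seed, drift_rate=1.5, n_proteins=700)
        drifted = generate_corpus(drifted_cfg)
        d_splits = build_splits(drifted["dag"], drifted["annotations"],
                                drifted_cfg.cutoff_year)
        d_na = d_splits["NA"][0]
        d_universe = common_term_universe(
            [s for group in d_splits.values() for s in group]
        )
        calm = discrepancy(na.train, na.test, universe).mean
        stormy = discrepancy(d_na.train, d_na.test, d_universe).mean
        hits += calm < stormy
    assert hits >= 2  # drift raises NA discrepancy in the clear majority


def test_cv_discrepancy_shrinks_with_corpus_size_without_drift():
    def mean_cv_disc(n):
        cfg = SyntheticConfig(seed=21, drift_rate=1.0, specificity_shift=0.0,
                              n_proteins=n)
        bundle = generate_corpus(cfg)
        splits = build_splits(bundle["dag"], bundle["annotations"], cfg.cutoff_year)
        universe = common_term_universe(
            [s for group in splits.values() for s in group]
        )
        prop = propagate_annotations(bundle["annotations"], bundle["dag"])
        prevalence = prop.term_counts() / len(prop.proteins)
        common = set(prevalence.index[prevalence >= 0.1]) & universe
        return (
            cv_discrepancy(splits["CV"], universe).mean,
            cv_discrepancy(splits["CV"], common).mean,
        )

    small_all, _ = mean_cv_disc(400)
    large_all, large_common = mean_cv_disc(1600)
    assert large_all < small_all  # fold-sampling noise shrinks with n
    assert large_common < 0.05  # and is small for well-populated terms


# -- network ----------------------------------------------------------------


def test_network_empty_when_density_and_coupling_zero():
    cfg = SyntheticConfig(seed=15, degree_coupling=0.0, edge_density=0.0, **SMALL)
    dag = generate_dag(cfg)
    records = generate_annotations(dag, cfg)
    assert generate_network(records, cfg, dag=dag) == []


def test_network_deterministic_under_seed():
    cfg = SyntheticConfig(seed=17, **SMALL)
    dag = generate_dag(cfg)
    records = generate_annotations(dag, cfg)
    assert generate_network(records, cfg, dag=dag) == generate_network(
        records, cfg, dag=dag
    )


def test_degree_coupling_links_degree_to_annotation_count():
    hits = 0
    for seed in range(5):
        cfg = SyntheticConfig(seed=seed, degree_coupling=1.0, n_proteins=500)
        dag = generate_dag(cfg)
        records = generate_annotations(dag, cfg)
        edges = generate_network(records, cfg, dag=dag)
        pre = propagate_annotations(records.before(cfg.cutoff_year), dag)
        counts = pre.records.groupby("protein")["term"].nunique()
        degree = pd.Series(0, index=sorted(records.proteins), dtype=float)
        for a, b in edges:
            degree[a] += 1
            degree[b] += 1
        shared = counts.reindex(degree.index).fillna(0)
        r, _ = pearsonr(degree.to_numpy(), shared.to_numpy())
        hits += r > 0.3
    assert hits >= 3


# -- similarity -------------------------------------------------------------


def test_similarity_identical_term_sets_get_strong_hit():
    cfg = SyntheticConfig(seed=19, **SMALL)
    twins = annotations(("a", "T1"), ("b", "T1"), ("a", "T2"), ("b", "T2"),
                        ("lone", "T3"), propagated=True)
    table = generate_similarity(twins, cfg)
    assert table.evalue("a", "b") is not None
    assert table.evalue("a", "b") <= 1e-10
    assert table.evalue("b", "a") == table.evalue("a", "b")


def test_similarity_protein_with_unique_terms_has_no_hits():
    cfg = SyntheticConfig(seed=19, **SMALL)
    twins = annotations(("a", "T1"), ("b", "T1"), ("lone", "T3"), propagated=True)
    table = generate_similarity(twins, cfg)
    assert "lone" not in table.queries


def test_similarity_evalues_within_declared_range():
    cfg = SyntheticConfig(seed=23, **SMALL)
    bundle = generate_corpus(cfg, with_similarity=True)
    values = [
        e for subjects in bundle["similarity"].hits.values()
        for e in subjects.values()
    ]
    assert values, "expected some hits in a coherent corpus"
    assert min(values) >= 1e-30 and max(values) <= 1e-3


def test_emax_features_separate_true_terms():
    cfg = SyntheticConfig(seed=25, **SMALL)
    bundle = generate_corpus(cfg, with_similarity=True)
    dag, records = bundle["dag"], bundle["annotations"]
    train = propagate_annotations(records.before(cfg.cutoff_year), dag)
    features = emax_features(bundle["similarity"], train)
    rng = np.random.default_rng(0)
    true_vals, random_vals = [], []
    pairs = train.pairs()
    terms = list(features.columns)
    for protein in features.index:
        for term in terms:
            value = features.at[protein, term]
            if (protein, term) in pairs:
                true_vals.append(value)
            elif rng.random() < 0.1:
                random_vals.append(value)
    assert np.mean(true_vals) > np.mean(random_vals)


# -- corpus round-trip ------------------------------------------------------


def test_write_corpus_round_trips_through_readers(tmp_path):
    cfg = SyntheticConfig(seed=27, **SMALL)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = write_corpus(cfg, tmp_path)
    dag = OntologyDAG.from_obo(str(tmp_path / "ontology.obo"))
    assert dag.terms == bundle["dag"].terms
    records = AnnotationSet.from_tsv(str(tmp_path / "annotations.tsv"))
    assert records.pairs() == bundle["annotations"].pairs()
    edges = read_edge_list(str(tmp_path / "network.tsv"))
    assert set(edges) == set(bundle["network"])
    sim = read_similarity_tsv(str(tmp_path / "similarity.tsv"))
    assert sim.queries == bundle["similarity"].queries
    assert (tmp_path / "manifest.json").exists()
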