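"""Ontology DAG, annotation propagation, filtering and score propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from afpbench import (
    AnnotationSet,
    OntologyDAG,
    ScoreTable,
    common_term_universe,
    filter_annotations,
    propagate_annotations,
    propagate_scores,
)
from conftest import annotations, parent_map_of, random_dag
from oracles import oracle_closure, oracle_propagate_pairs, oracle_propagate_scores


# -- DAG construction -------------------------------------------------------


def test_cycle_rejected():
    with pytest.raises(ValueError, match="cycle"):
        OntologyDAG([("A", "B"), ("B", "A")], {"A": "P", "B": "P"})


def test_cross_namespace_edge_rejected():
    with pytest.raises(ValueError, match="cross-namespace"):
        OntologyDAG([("A", "B")], {"A": "P", "B": "F"})


def test_roots_found_per_namespace(diamond_dag):
    assert diamond_dag.roots == {"P": "root"}
    assert diamond_dag.is_root("root") and not diamond_dag.is_root("A")


def test_ancestor_and_descendant_queries(diamond_dag):
    assert diamond_dag.ancestors("D") == {"B", "C", "A", "root"}
    assert diamond_dag.descendants("A") == {"B", "C", "D"}
    with pytest.raises(KeyError, match="unknown ontology term"):
        diamond_dag.ancestors("nope")


# -- annotation propagation -------------------------------------------------


def test_propagation_chain(chain_dag):
    result = propagate_annotations(annotations(("p", "B")), chain_dag)
    assert result.pairs() == {("p", "B"), ("p", "A")}
    assert result.propagated


def test_propagation_diamond(diamond_dag):
    result = propagate_annotations(annotations(("p", "D")), diamond_dag)
    assert result.pairs() == {("p", "D"), ("p", "B"), ("p", "C"), ("p", "A")}


def test_propagation_idempotent(diamond_dag):
    once = propagate_annotations(annotations(("p", "D"), ("q", "B")), diamond_dag)
    twice = propagate_annotations(once, diamond_dag)
    pd.testing.assert_frame_equal(once.records, twice.records)


def test_propagation_drops_root_annotation(chain_dag):
    result = propagate_annotations(annotations(("p", "root")), chain_dag)
    assert len(result) == 0


def test_propagation_unknown_term_named(chain_dag):
    with pytest.raises(KeyError, match="X99"):
        propagate_annotations(annotations(("p", "X99")), chain_dag)


def test_propagation_matches_oracle_on_random_dags():
    rng = np.random.default_rng(7)
    for _ in range(25):
        dag = random_dag(rng, int(rng.integers(3, 21)))
        terms = sorted(dag.terms)
        pairs = [
            (f"p{rng.integers(3)}", terms[rng.integers(len(terms))])
            for _ in range(6)
        ]
        got = propagate_annotations(
            annotations(*[(p, t) for p, t in pairs]), dag
        ).pairs()
        expected = oracle_propagate_pairs(
            pairs, parent_map_of(dag), dag.root_terms
        )
        assert got == expected


# -- closure properties -----------------------------------------------------


@settings(deadline=None, derandomize=True)
@given(st.data())
def test_closure_idempotent_and_monotone(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
    dag = random_dag(rng, data.draw(st.integers(min_value=3, max_value=20)))
    terms = sorted(dag.terms)
    subset = data.draw(st.sets(st.sampled_from(terms), max_size=6))
    closed = dag.closure(subset)
    assert dag.closure(closed) == closed
    assert closed >= (set(subset) - dag.root_terms)
    assert closed == oracle_closure(subset, parent_map_of(dag), dag.root_terms)


# -- score propagation ------------------------------------------------------


def _table(rows: dict[str, dict[str, float]]) -> ScoreTable:
    return ScoreTable(pd.DataFrame(rows).T.fillna(0.0))


def test_score_propagation_chain(chain_dag):
    out = propagate_scores(_table({"p": {"B": 0.7, "A": 0.4}}), chain_dag)
    assert out.score("p", "A") == pytest.approx(0.7)
    assert out.score("p", "B") == pytest.approx(0.7)


def test_score_propagation_no_change_when_monotone(chain_dag):
    out = propagate_scores(_table({"p": {"B": 0.2, "A": 0.9}}), chain_dag)
    assert out.score("p", "A") == pytest.approx(0.9)
    assert out.score("p", "B") == pytest.approx(0.2)


def test_score_propagation_diamond(diamond_dag):
    out = propagate_scores(
        _table({"p": {"D": 0.6, "B": 0.1, "C": 0.3, "A": 0.0}}), diamond_dag
    )
    for term in ["D", "B", "C", "A"]:
        assert out.score("p", term) == pytest.approx(0.6)


def test_scores_outside_unit_interval_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ScoreTable(pd.DataFrame({"B": [1.5]}, index=["p"]))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        ScoreTable(pd.DataFrame({"B": [-0.1]}, index=["p"]))


def test_score_propagation_matches_oracle_and_is_idempotent():
    rng = np.random.default_rng(11)
    for _ in range(25):
        dag = random_dag(rng, int(rng.integers(3, 21)))
        terms = sorted(dag.terms)
        scores = {
            f"p{i}": {
                t: float(np.round(rng.random(), 3))
                for t in rng.choice(terms, size=min(5, len(terms)), replace=False)
            }
            for i in range(3)
        }
        out = propagate_scores(_table(scores), dag)
        expected = oracle_propagate_scores(
            scores, parent_map_of(dag), dag.root_terms, dag.terms
        )
        for protein, term_scores in expected.items():
            for term, value in term_scores.items():
                assert out.score(protein, term) == pytest.approx(value)
        # parent >= child along every edge, and idempotence
        again = propagate_scores(out, dag)
        pd.testing.assert_frame_equal(out.values, again.values)
        for term in out.terms:
            for parent in dag.parents(term):
                if dag.is_root(parent):
                    continue
                col_p = out.values[parent] if parent in out.values.columns else 0.0
                assert np.all(np.asarray(col_p) + 1e-12 >= out.values[term].to_numpy())


# -- filtering --------------------------------------------------------------


def test_filter_removes_root_annotations(chain_dag):
    result = filter_annotations(annotations(("p1", "root", "IDA", 2008)), chain_dag)
    assert len(result) == 0  # roots are ignored; empty result is valid


def test_filter_removes_computational_evidence(chain_dag):
    result = filter_annotations(annotations(("p1", "A", "IEA", 2008)), chain_dag)
    assert len(result) == 0


def test_filter_keeps_experimental_evidence_and_propagates(chain_dag):
    result = filter_annotations(annotations(("p1", "B", "EXP", 2008)), chain_dag)
    assert result.pairs() == {("p1", "B"), ("p1", "A")}


def test_filter_min_proteins_on_propagated_set(wide_dag):
    # 12 proteins annotated to A1 (hence A), 3 to B1 (hence B); with
    # min_proteins=10 only the A branch survives.
    records = [(f"a{i}", "A1") for i in range(12)] + [(f"b{i}", "B1") for i in range(3)]
    result = filter_annotations(annotations(*records), wide_dag, min_proteins=10)
    assert result.terms == {"A1", "A"}
    assert len({p for p, _ in result.pairs()}) == 12


def test_filter_excluded_term_also_removed_after_propagation(chain_dag):
    # excluding A removes both direct A records and A pairs implied by B
    result = filter_annotations(
        annotations(("p1", "B"), ("p2", "A")), chain_dag, excluded_terms={"A"}
    )
    assert result.pairs() == {("p1", "B")}


def test_filter_unknown_term_is_an_error(chain_dag):
    with pytest.raises(KeyError, match="Zzz"):
        filter_annotations(annotations(("p1", "Zzz")), chain_dag)


# -- common term universe ---------------------------------------------------


class _FakeSplit:
    def __init__(self, train, test):
        self.train, self.test = train, test


def test_common_universe_intersection():
    splits = [
        _FakeSplit(annotations(("p", "A")), annotations(("p", "B"))),
        _FakeSplit(annotations(("p", "A"), ("p", "C")), annotations()),
        _FakeSplit(annotations(("q", "A")), annotations()),
    ]
    assert common_term_universe(splits) == {"A"}


def test_common_universe_identical_setups():
    split = _FakeSplit(annotations(("p", "A"), ("p", "B")), annotations())
    assert common_term_universe([split, split]) == {"A", "B"}


def test_common_universe_empty_warns():
    splits = [
        _FakeSplit(annotations(("p", "A")), annotations()),
        _FakeSplit(annotations(("p", "B")), annotations()),
    ]
    with pytest.warns(UserWarning, match="empty"):
        assert common_term_universe(splits) == frozenset()


def test_common_universe_needs_two_splits():
    with pytest.raises(ValueError):
        common_term_universe([_FakeSplit(annotations(("p", "A")), annotations())])


# -- IO ---------------------------------------------------------------------


def test_obo_round_trip(tmp_path, diamond_dag):
    path = tmp_path / "toy.obo"
    diamond_dag.to_obo(path)
    loaded = OntologyDAG.from_obo(str(path))
    assert loaded.terms == diamond_dag.terms
    assert {(c, p) for c in loaded.terms for p in loaded.parents(c)} == {
        (c, p) for c in diamond_dag.terms for p in diamond_dag.parents(c)
    }


def test_gaf_reader(tmp_path):
    gaf = tmp_path / "toy.gaf"
    row = ["DB", "P12345", "SYMB", "", "GO:0001", "REF", "IDA", "", "P",
           "", "", "protein", "taxon:9606", "20081231", "UniProt"]
    gaf.write_text("!gaf-version: 2.1\n" + "\t".join(row) + "\n")
    records = AnnotationSet.from_gaf(str(gaf))
    assert records.records.iloc[0].tolist() == ["P12345", "GO:0001", "IDA", 2008]


def test_annotation_tsv_round_trip(tmp_path):
    original = annotations(("p1", "A", "EXP", 2007), ("p2", "B", "TAS", 2012))
    path = tmp_path / "ann.tsv"
    original.to_tsv(path)
    loaded = AnnotationSet.from_tsv(str(path))
    pd.testing.assert_frame_equal(loaded.records, original.records)


def test_annotation_validation():
    with pytest.raises(ValueError, match="year"):
        AnnotationSet.from_records([("p", "A", "IDA", -3)])
    with pytest.raises(ValueError, match="evidence"):
        AnnotationSet.from_records([("p", "A", "", 2005)])
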